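"""Synthetic swimming-performance data with a known reaction-norm structure.

Generates tidy observation tables for a repeated-measures thermal-acclimation
design: each fish is acclimated consecutively to a cool (20 °C) and a warm
(28 °C) treatment and swum at three acute test temperatures (20, 28, 32 °C).
The standardized critical swimming speed (Ucrit, body lengths per second)
follows a quadratic thermal reaction norm with individual random effects
dominated by variation in the acclimation response, plus residual noise.

Also provides a simulator of the stepped incremental-velocity flume protocol
that defines Ucrit operationally.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Fixed-effect term names, in model order. ``sex`` is coded 0 = female,
#: 1 = male; ``AT`` is 0 for the cool and 1 for the warm acclimation
#: treatment; ``TT`` is test temperature centered at 28 °C.
FIXED_TERMS = ("intercept", "sex", "TT", "TT2", "AT", "AT:TT", "AT:TT2")

#: Random-effect term names of the richest individual structure: an overall
#: intercept plus an acclimation-specific shift, slope change and curvature
#: change (all relative to the cool treatment).
RANDOM_TERMS = ("intercept", "AT", "AT:TT", "AT:TT2")

#: Columns of the canonical observation CSV.
CSV_COLUMNS = ("fish_id", "sex", "accl_temp_c", "test_temp_c", "ucrit_bl_s")

TT_CENTER = 28.0
UCRIT_FLOOR_BL_S = 0.1

#: Acclimation-treatment dummy coding (°C -> 0/1).
AT_CODE = {20.0: 0.0, 28.0: 1.0}
SEX_CODE = {"female": 0.0, "male": 1.0}


class ConfigurationError(ValueError):
    """Invalid simulation parameters (e.g. a non-PSD correlation matrix)."""


class NonSwimmerError(ValueError):
    """A fish whose capacity is below the protocol's starting speed."""


@dataclass
class SimulationParams:
    """Generative parameters of the synthetic reaction-norm dataset.

    Coefficients ``beta0``–``beta6`` act on the standardized-performance
    scale and follow the fixed-term order of :data:`FIXED_TERMS`. Random
    effect standard deviations follow :data:`RANDOM_TERMS`; ``re_corr`` is
    their correlation matrix. ``raw_mean``/``raw_sd`` give the affine map
    back to body lengths per second.
    """

    beta0: float = 0.49
    beta1: float = -0.33   # sex (male relative to female)
    beta2: float = -0.076  # TT, linear slope
    beta3: float = -0.024  # TT^2, curvature
    beta4: float = 0.27    # AT, vertical shift under warm acclimation
    beta5: float = 0.15    # AT:TT, slope change under warm acclimation
    beta6: float = 0.011   # AT:TT^2, curvature change under warm acclimation
    re_sd_intercept: float = 0.5
    re_sd_at: float = 0.4
    re_sd_tt_at: float = 0.12
    re_sd_tt2_at: float = 0.025
    re_corr: np.ndarray = field(default_factory=lambda: np.eye(4))
    resid_sd: float = 0.5
    raw_mean: float = 7.0  # BL s^-1
    raw_sd: float = 2.0    # BL s^-1
    n_fish: int = 48
    prop_male: float = 20 / 48
    test_temps: Sequence[float] = (20.0, 28.0, 32.0)
    accl_temps: Sequence[float] = (20.0, 28.0)
    dropout_rate: float = 0.0
    seed: int = 0

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3,
                         self.beta4, self.beta5, self.beta6])

    @property
    def re_sds(self) -> np.ndarray:
        return np.array([self.re_sd_intercept, self.re_sd_at,
                         self.re_sd_tt_at, self.re_sd_tt2_at])

    @property
    def re_cov(self) -> np.ndarray:
        """Random-effect covariance matrix implied by the SDs and correlation."""
        d = np.diag(self.re_sds)
        return d @ np.asarray(self.re_corr, dtype=float) @ d

    def validate(self) -> None:
        if any(s < 0 for s in self.re_sds) or self.resid_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.raw_sd <= 0:
            raise ConfigurationError("raw_sd must be > 0")
        if not 0.0 <= self.prop_male <= 1.0:
            raise ConfigurationError("prop_male must lie in [0, 1]")
        if self.n_fish < 1:
            raise ConfigurationError("n_fish must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        corr = np.asarray(self.re_corr, dtype=float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise ConfigurationError("re_corr must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ConfigurationError("re_corr must have a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("re_corr must be positive semi-definite")
        for a in self.accl_temps:
            if float(a) not in AT_CODE:
                raise ConfigurationError(
                    f"acclimation temperature {a} is not a coded treatment "
                    f"(valid: {sorted(AT_CODE)})")

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ProtocolParams:
    """Settings of the stepped incremental-velocity Ucrit protocol."""

    u_start: float = 6.0     # cm s^-1
    t_start: float = 1200.0  # s at the starting speed
    u_i: float = 2.0         # cm s^-1 speed increment
    t_i: float = 300.0       # s per increment
    body_length: float = 2.5  # cm

    def validate(self) -> None:
        if self.u_i <= 0 or self.t_i <= 0:
            raise ConfigurationError("u_i and t_i must be > 0")
        if self.body_length <= 0:
            raise ConfigurationError("body_length must be > 0")


def default_params(seed: int = 0) -> SimulationParams:
    """Default generative parameters.

    The fixed-effect coefficients equal the published reaction-norm
    estimates for the mosquitofish dataset the generator emulates; the
    random-effect magnitudes are generator choices sized so that
    acclimation-response variation dominates individual differences.
    """
    return SimulationParams(seed=seed)


def fixed_effect_mean(beta: np.ndarray, sex_male: float, at: float,
                      tt: float) -> float:
    """Mean standardized performance at one design point."""
    return float(beta[0] + beta[1] * sex_male + beta[2] * tt
                 + beta[3] * tt ** 2
                 + at * (beta[4] + beta[5] * tt + beta[6] * tt ** 2))


def _re_transform(params: SimulationParams) -> np.ndarray:
    """Matrix L with L L' = random-effect covariance (PSD-safe)."""
    cov = params.re_cov
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        if w.min() < -1e-10:
            raise ConfigurationError("random-effect covariance is not PSD")
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_dataset(params: SimulationParams | None = None) -> pd.DataFrame:
    """Simulate one observation table under the quadratic reaction norm.

    Returns one row per fish x acclimation x test temperature with both the
    generator-scale standardized value (``ucrit_z``) and the back-transformed
    raw performance (``ucrit_bl_s``, floored at a small positive value).
    Deterministic given ``params.seed``; each fish consumes an independent
    child random stream, so per-fish draws are stable under reordering.
    """
    if params is None:
        params = default_params()
    params.validate()
    L = _re_transform(params)
    root = np.random.SeedSequence(params.seed)
    streams = root.spawn(params.n_fish)

    n_male = int(round(params.prop_male * params.n_fish))
    rows = []
    for j in range(params.n_fish):
        rng = np.random.default_rng(streams[j])
        b = L @ rng.standard_normal(4)
        sex = "male" if j < n_male else "female"
        sex_code = SEX_CODE[sex]
        for accl in params.accl_temps:
            if params.dropout_rate > 0 and rng.random() < params.dropout_rate:
                continue  # pump failure: the whole fish x acclimation block
            at = AT_CODE[float(accl)]
            for temp in params.test_temps:
                tt = float(temp) - TT_CENTER
                mu = fixed_effect_mean(params.beta, sex_code, at, tt)
                re_part = b[0] + at * (b[1] + b[2] * tt + b[3] * tt ** 2)
                z = mu + re_part + params.resid_sd * rng.standard_normal()
                raw = max(params.raw_mean + params.raw_sd * z,
                          UCRIT_FLOOR_BL_S)
                rows.append((f"fish{j + 1:03d}", sex, float(accl),
                             float(temp), tt, raw, z))
    return pd.DataFrame(rows, columns=["fish_id", "sex", "accl_temp_c",
                                       "test_temp_c", "tt", "ucrit_bl_s",
                                       "ucrit_z"])


def write_observations(table: pd.DataFrame, path) -> None:
    """Write the canonical 5-column observation CSV."""
    table.loc[:, list(CSV_COLUMNS)].to_csv(path, index=False)


def protocol_steps(true_ucrit_cm_s: float,
                   protocol: ProtocolParams) -> tuple[float, float]:
    """Decompose a true critical speed into (U_f, T_f) under the protocol.

    U_f is the highest increment speed the fish completes in full and T_f
    the time survived in the failing interval, so that
    ``U_f + T_f / t_i * u_i`` reproduces the input speed.
    """
    protocol.validate()
    if true_ucrit_cm_s < protocol.u_start:
        raise NonSwimmerError(
            f"true Ucrit {true_ucrit_cm_s} cm/s is below the starting "
            f"speed {protocol.u_start} cm/s")
    n_full = math.floor((true_ucrit_cm_s - protocol.u_start) / protocol.u_i)
    u_f = protocol.u_start + n_full * protocol.u_i
    t_f = (true_ucrit_cm_s - u_f) / protocol.u_i * protocol.t_i
    return u_f, t_f


def ucrit_from_trial(u_f: float, t_f: float,
                     protocol: ProtocolParams) -> float:
    """Incremental-velocity formula: Ucrit = U_f + T_f/T_i * U_i (cm/s)."""
    protocol.validate()
    if not 0.0 <= t_f <= protocol.t_i:
        raise ValueError("t_f must lie in [0, t_i]")
    return u_f + t_f / protocol.t_i * protocol.u_i


def simulate_ucrit_trial(true_ucrit_cm_s: float,
                         protocol: ProtocolParams | None = None) -> float:
    """Run a noise-free stepped trial and return measured Ucrit in BL s^-1.

    Inverse composition: the step decomposition followed by the Ucrit
    formula recovers the input speed exactly, then converts to body lengths
    per second.
    """
    if protocol is None:
        protocol = ProtocolParams()
    u_f, t_f = protocol_steps(true_ucrit_cm_s, protocol)
    return ucrit_from_trial(u_f, t_f, protocol) / protocol.body_length
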