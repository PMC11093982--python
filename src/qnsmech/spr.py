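"""1:1 Langmuir surface-plasmon-resonance kinetics.

The single-site model dR/dt = ka·C·(Rmax − R) − kd·R has the closed-form
association phase R(t) = Req·(1 − exp(−(ka·C + kd)·t)) with
Req = Rmax·C/(C + KD), and exponential dissociation after the analyte
injection ends.  Sensorgrams at several analyte concentrations are fit
globally by nonlinear least squares over (ka, kd, Rmax); the equilibrium
dissociation constant is reported as the ratio KD = kd/ka.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "KineticFit",
    "simulate_sensorgram",
    "fit_langmuir",
    "equilibrium_response",
    "read_sensorgrams_csv",
    "write_sensorgrams_csv",
]


@dataclass
class Sensorgram:
    times: np.ndarray  # s
    response: np.ndarray  # RU
    analyte_conc: float  # M
    t_assoc_end: float  # s
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.response.shape:
            raise ValueError("times and response must have equal length")
        if self.t_assoc_end <= self.times[0]:
            raise ValueError("association phase must precede dissociation")


@dataclass
class KineticFit:
    ka: float  # 1/(M s)
    kd: float  # 1/s
    rmax: float  # RU
    rss: float  # RU^2
    stderr: dict[str, float] = field(default_factory=dict)
    n_points: int = 0
    warning: str | None = None

    def __post_init__(self) -> None:
        if min(self.ka, self.kd, self.rmax) <= 0:
            raise ValueError("ka, kd and Rmax must be positive")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant, exactly kd/ka (M)."""
        return self.kd / self.ka


def equilibrium_response(rmax: float, kd_const: float, conc: float) -> float:
    """Langmuir isotherm plateau Rmax·C/(C + KD) in RU."""
    if min(rmax, kd_const, conc) < 0:
        raise ValueError("arguments must be non-negative")
    return rmax * conc / (conc + kd_const)


def _model_curve(
    ka: float, kd: float, rmax: float, conc: float, times: np.ndarray, t_end: float
) -> np.ndarray:
    kobs = ka * conc + kd
    req = rmax * conc / (conc + kd / ka)
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(times, t_end)))
    r_end = req * (1.0 - np.exp(-kobs * t_end))
    dissoc = r_end * np.exp(-kd * (times - t_end))
    return np.where(times <= t_end, assoc, dissoc)


def simulate_sensorgram(
    ka: float,
    kd: float,
    rmax: float,
    conc: float,
    times: Sequence[float],
    t_assoc_end: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Sensorgram:
    """Closed-form 1:1 sensorgram with optional seeded Gaussian noise."""
    if min(ka, kd, rmax, conc) <= 0:
        raise ValueError("rates, Rmax and concentration must be positive")
    times = np.asarray(times, dtype=float)
    response = _model_curve(ka, kd, rmax, conc, times, t_assoc_end)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=times.shape)
    return Sensorgram(times, response, conc, t_assoc_end, noise_sd, seed)


def fit_langmuir(sensorgrams: Sequence[Sensorgram]) -> KineticFit:
    """Global nonlinear least-squares fit of (ka, kd, Rmax) across all
    concentrations of one analyte series; Rmax is shared (one immobilized
    surface).  KD is reported as kd/ka."""
    if not sensorgrams:
        raise ValueError("need at least one sensorgram")
    warning = None
    if len({s.analyte_conc for s in sensorgrams}) < 2:
        warning = "single analyte concentration: ka and kd weakly identifiable"

    r_scale = max(float(np.max(np.abs(s.response))) for s in sensorgrams)
    r_scale = r_scale if r_scale > 0 else 1.0
    c_mid = float(np.median([s.analyte_conc for s in sensorgrams]))
    t_span = max(float(s.times[-1] - s.times[0]) for s in sensorgrams)

    def residuals(logp: np.ndarray) -> np.ndarray:
        ka, kd, rmax = np.exp(logp)
        out = []
        for s in sensorgrams:
            out.append(
                _model_curve(ka, kd, rmax, s.analyte_conc, s.times, s.t_assoc_end)
                - s.response
            )
        return np.concatenate(out)

    x0 = np.log([1.0 / (c_mid * t_span), 1.0 / t_span, r_scale])
    res = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success and res.status <= 0:
        raise RuntimeError(f"Langmuir fit did not converge: {res.message}")
    ka, kd, rmax = np.exp(res.x)
    rss = float(res.fun @ res.fun)

    n = sum(s.times.size for s in sensorgrams)
    stderr: dict[str, float] = {}
    try:
        dof = max(n - 3, 1)
        cov_log = np.linalg.inv(res.jac.T @ res.jac) * rss / dof
        sd_log = np.sqrt(np.diag(cov_log))
        # delta method back to linear scale
        for name, val, sl in zip(("ka", "kd", "rmax"), (ka, kd, rmax), sd_log):
            stderr[name] = float(val * sl)
    except np.linalg.LinAlgError:
        pass
    return KineticFit(
        ka=float(ka), kd=float(kd), rmax=float(rmax), rss=rss, stderr=stderr,
        n_points=n, warning=warning,
    )


# ---------------------------------------------------------------------------
# CSV I/O — columns: time_s, response_RU, conc_M, phase


def write_sensorgrams_csv(sensorgrams: Sequence[Sensorgram], path: str | Path) -> None:
    frames = []
    for s in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.times,
                    "response_RU": s.response,
                    "conc_M": s.analyte_conc,
                    "phase": np.where(s.times <= s.t_assoc_end, "assoc", "dissoc"),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgrams_csv(path: str | Path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    needed = {"time_s", "response_RU", "conc_M", "phase"}
    if not needed.issubset(df.columns):
        raise ValueError(f"sensorgram CSV must have columns {sorted(needed)}")
    out = []
    for conc, grp in df.groupby("conc_M", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "assoc"]
        t_end = float(assoc["time_s"].max()) if not assoc.empty else float(grp["time_s"].iloc[0])
        out.append(
            Sensorgram(
                grp["time_s"].to_numpy(),
                grp["response_RU"].to_numpy(),
                float(conc),
                t_end,
            )
        )
    return out
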