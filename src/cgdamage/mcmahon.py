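"""Plasmid dose-response model and strand-break yield fitting.

Agarose-gel band fractions of supercoiled (SC), open-circular (OC) and
linear (L) plasmid forms evolve with dose D as

    SC(D) = S0 exp(-(mu + phi) D)
    OC(D) = exp(-phi D) [ exp(-0.5 mu^2 rho D^2) (S0 + C0) - S0 exp(-mu D) ]
    L(D)  = 1 - (S0 + C0) exp(-(phi D + 0.5 mu^2 rho D^2))

where mu and phi are the mean SSB and DSB yields per plasmid per Gy, rho
is the probability that two independent SSBs sit on opposite strands
within the DSB pairing window (10 bp), and S0/C0 are the unirradiated SC
and OC fractions.  The three fractions sum to one identically.

mu and phi are extracted by nonlinear least squares on the OC(D) curve
(the best-constrained band); rho is held fixed — by default the
opposite-strand site fraction (2w+1)/n_bp for a window of w = 10 bp on a
plasmid of n_bp base pairs.  Per-plasmid yields convert to per-Gbp as
yield / (n_bp * 1e-9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

PBR322_BP = 4361
PAIRING_WINDOW_BP = 10


def default_rho(n_bp: int = PBR322_BP, window_bp: int = PAIRING_WINDOW_BP) -> float:
    """Opposite-strand within-window site fraction: (2w + 1) / n_bp."""
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    return (2 * window_bp + 1) / n_bp


def sc_fraction(d, s0, mu, phi):
    """Supercoiled fraction SC(D)."""
    d = np.asarray(d, dtype=float)
    return s0 * np.exp(-(mu + phi) * d)


def oc_fraction(d, s0, c0, mu, phi, rho):
    """Open-circular fraction OC(D)."""
    d = np.asarray(d, dtype=float)
    return np.exp(-phi * d) * (
        np.exp(-0.5 * mu**2 * rho * d**2) * (s0 + c0) - s0 * np.exp(-mu * d)
    )


def l_fraction(d, s0, c0, mu, phi, rho):
    """Linear fraction L(D)."""
    d = np.asarray(d, dtype=float)
    return 1.0 - (s0 + c0) * np.exp(-(phi * d + 0.5 * mu**2 * rho * d**2))


@dataclass
class GelDataset:
    doses: np.ndarray  # (n,) Gy
    sc: np.ndarray
    oc: np.ndarray
    lin: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.sc = np.asarray(self.sc, dtype=float)
        self.oc = np.asarray(self.oc, dtype=float)
        self.lin = np.asarray(self.lin, dtype=float)
        if not (len(self.doses) == len(self.sc) == len(self.oc) == len(self.lin)):
            raise ValueError("dose and fraction arrays must have equal length")
        sums = self.sc + self.oc + self.lin
        if np.any(np.abs(sums - 1.0) > 0.05):
            raise ValueError("SC + OC + L must sum to 1 within measurement tolerance")

    @property
    def s0(self) -> float:
        return float(self.sc[np.argmin(self.doses)])

    @property
    def c0(self) -> float:
        return float(self.oc[np.argmin(self.doses)])


@dataclass
class McMahonFit:
    mu: float  # SSB yield, per plasmid per Gy
    phi: float  # DSB yield, per plasmid per Gy
    rho: float
    s0: float
    c0: float
    covariance: np.ndarray
    r_squared: float
    sse: float

    def per_gbp(self, n_bp: int = PBR322_BP) -> tuple[float, float]:
        """(mu, phi) converted to Gy^-1 Gbp^-1 for a plasmid of n_bp."""
        return per_gbp(self.mu, n_bp), per_gbp(self.phi, n_bp)


def per_gbp(yield_per_plasmid: float, n_bp: int) -> float:
    """Per-plasmid-per-Gy yield -> per-Gy-per-Gbp."""
    return yield_per_plasmid / (n_bp * 1e-9)


def per_plasmid(yield_per_gbp: float, n_bp: int) -> float:
    """Per-Gy-per-Gbp yield -> per-plasmid-per-Gy."""
    return yield_per_gbp * n_bp * 1e-9


def fit_oc(
    data: GelDataset,
    rho: float,
    init_grid: tuple = None,
    bounds: tuple = (0.0, np.inf),
) -> McMahonFit:
    """Fit (mu, phi) to the OC(D) band by nonlinear least squares.

    S0 and C0 are taken from the zero-dose lane.  A multi-start over
    ``init_grid`` (pairs of (mu, phi) starting values; a log-spaced grid
    scaled to the dose range by default) guards against local minima;
    the best-SSE solution wins.
    """
    if len(data.doses) < 4:
        raise ValueError("need at least 4 dose points")
    if np.all(data.oc == 0):
        raise ValueError("degenerate fit: OC band is identically zero")
    s0, c0 = data.s0, data.c0
    dmax = float(data.doses.max())
    if dmax <= 0:
        raise ValueError("need a positive maximum dose")
    if init_grid is None:
        scales = np.array([0.1, 0.5, 2.0, 8.0]) / dmax
        init_grid = [(m, p) for m in scales for p in scales / 4.0]

    def model(d, mu, phi):
        return oc_fraction(d, s0, c0, mu, phi, rho)

    best = None
    for mu0, phi0 in init_grid:
        try:
            popt, pcov = curve_fit(
                model,
                data.doses,
                data.oc,
                p0=(mu0, phi0),
                bounds=bounds,
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = data.oc - model(data.doses, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise RuntimeError(
            "OC(D) fit did not converge from any starting point; "
            f"tried {len(init_grid)} starts with rho={rho:g}"
        )
    popt, pcov, sse = best
    sst = float(np.sum((data.oc - data.oc.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return McMahonFit(
        mu=float(popt[0]),
        phi=float(popt[1]),
        rho=rho,
        s0=s0,
        c0=c0,
        covariance=pcov,
        r_squared=r2,
        sse=sse,
    )


def generate_gel_data(
    mu: float,
    phi: float,
    rho: float,
    s0: float,
    c0: float,
    doses,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> GelDataset:
    """Synthetic gel band fractions from the forward model plus noise.

    Gaussian noise (sd = ``noise_sd``) is added to each band, clipped to
    be non-negative and renormalized so the three bands sum to one.
    """
    if min(mu, phi, rho, s0, c0, noise_sd) < 0:
        raise ValueError("parameters must be non-negative")
    doses = np.asarray(doses, dtype=float)
    sc = sc_fraction(doses, s0, mu, phi)
    oc = oc_fraction(doses, s0, c0, mu, phi, rho)
    lin = l_fraction(doses, s0, c0, mu, phi, rho)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        sc = np.clip(sc + rng.normal(0, noise_sd, sc.shape), 0, None)
        oc = np.clip(oc + rng.normal(0, noise_sd, oc.shape), 0, None)
        lin = np.clip(lin + rng.normal(0, noise_sd, lin.shape), 0, None)
        total = sc + oc + lin
        sc, oc, lin = sc / total, oc / total, lin / total
    return GelDataset(doses=doses, sc=sc, oc=oc, lin=lin)


def read_gel_csv(path: str | Path) -> GelDataset:
    """Read a gel band-fraction CSV with columns dose_Gy, sc, oc, l."""
    df = pd.read_csv(path)
    required = ["dose_Gy", "sc", "oc", "l"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return GelDataset(
        doses=df["dose_Gy"].to_numpy(float),
        sc=df["sc"].to_numpy(float),
        oc=df["oc"].to_numpy(float),
        lin=df["l"].to_numpy(float),
    )


def write_gel_csv(data: GelDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"dose_Gy": data.doses, "sc": data.sc, "oc": data.oc, "l": data.lin}
    ).to_csv(path, index=False)
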