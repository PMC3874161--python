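"""Michaelis–Menten aminoacylation fits and relative catalytic efficiency.

Aminoacylation assays report initial velocities at a series of substrate
(tRNA) concentrations; fitting v = kcat·E·[S]/(Km+[S]) yields kcat (min⁻¹)
and Km (µM), and kcat/Km (µM⁻¹·min⁻¹) ranks tRNA variants as synthetase
substrates.  Relative efficiency — a variant's kcat/Km as a percent of a
reference tRNA's, integer-rounded — is how such comparisons are tabulated.

The enzyme concentration E cannot be inferred from velocity data alone; it
is an explicit input (default 1, in which case "kcat" is Vmax in the
velocity's own units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class KineticsFit:
    kcat: float                  # min^-1 (per enzyme, when E is supplied)
    km: float                    # µM
    se_kcat: float = float("nan")
    se_km: float = float("nan")
    converged: bool = True
    enzyme_conc: float = 1.0

    @property
    def kcat_over_km(self) -> float:
        return self.kcat / self.km

    @property
    def se_kcat_over_km(self) -> float:
        # first-order propagation, covariance ignored
        eff = self.kcat_over_km
        return abs(eff) * np.sqrt(
            (self.se_kcat / self.kcat) ** 2 + (self.se_km / self.km) ** 2
        )

    @classmethod
    def from_constants(cls, kcat: float, km: float) -> "KineticsFit":
        """Wrap published constants (no fit) for efficiency arithmetic."""
        return cls(kcat=kcat, km=km, se_kcat=0.0, se_km=0.0)


def _mm(s, kcat, km, enzyme):
    return kcat * enzyme * s / (km + s)


def fit_michaelis_menten(
    substrate: Sequence[float],
    velocity: Sequence[float],
    enzyme_conc: float = 1.0,
    init: Optional[Tuple[float, float]] = None,
) -> KineticsFit:
    """Least-squares fit of v = kcat·E·S/(Km+S).

    Requires >=3 distinct substrate levels and non-negative velocities.
    Standard errors come from the curvature (covariance) of the fit.
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if s.shape != v.shape or s.ndim != 1:
        raise ValueError("substrate and velocity must be equal-length 1-D")
    if len(np.unique(s)) < 3:
        raise ValueError("need >=3 distinct substrate concentrations")
    if np.any(v < 0):
        raise ValueError("velocities must be non-negative")
    if init is None:
        vmax0 = float(v.max()) or 1.0
        # substrate level nearest half-saturation as the Km guess
        km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))]) or float(np.median(s))
        init = (vmax0 / enzyme_conc, km0)
    try:
        popt, pcov = curve_fit(
            lambda x, kcat, km: _mm(x, kcat, km, enzyme_conc),
            s,
            v,
            p0=init,
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    return KineticsFit(
        kcat=float(popt[0]),
        km=float(popt[1]),
        se_kcat=float(se[0]),
        se_km=float(se[1]),
        converged=True,
        enzyme_conc=enzyme_conc,
    )


def relative_efficiency(
    fit: Union[KineticsFit, float], reference: Union[KineticsFit, float]
) -> int:
    """100 · (kcat/Km) / (kcat/Km)_ref, rounded to the nearest integer.

    Accepts fitted objects or bare kcat/Km values; a fit compared with
    itself is exactly 100.
    """
    eff = fit.kcat_over_km if isinstance(fit, KineticsFit) else float(fit)
    ref = reference.kcat_over_km if isinstance(reference, KineticsFit) else float(reference)
    if ref <= 0:
        raise ValueError("reference kcat/Km must be positive")
    return int(round(100.0 * eff / ref))


def velocities_from_timecourse(
    time: Sequence[float],
    product: Sequence[float],
    window: int = 3,
) -> float:
    """Initial velocity as the linear slope over the first ``window`` points
    of a product-vs-time course."""
    t = np.asarray(time, dtype=float)[:window]
    p = np.asarray(product, dtype=float)[:window]
    if len(t) < 2:
        raise ValueError("need >=2 early time points for a slope")
    slope = np.polyfit(t, p, 1)[0]
    return float(slope)


def read_velocity_tsv(path):
    """Read a (substrate, velocity) or (time, product, substrate) TSV.

    Returns (substrate, velocity) arrays; time-course input is collapsed to
    one initial velocity per substrate level.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower() for c in df.columns}
    df.columns = [c.lower() for c in df.columns]
    if {"substrate", "velocity"} <= cols:
        return df["substrate"].to_numpy(float), df["velocity"].to_numpy(float)
    if {"time", "product", "substrate"} <= cols:
        subs, vels = [], []
        for s_level, grp in df.groupby("substrate", sort=True):
            grp = grp.sort_values("time")
            subs.append(float(s_level))
            vels.append(velocities_from_timecourse(grp["time"], grp["product"]))
        return np.asarray(subs), np.asarray(vels)
    raise ValueError(
        "TSV must have columns (substrate, velocity) or (time, product, substrate)"
    )


def fit_table_tsv(fits, labels, reference_label, path) -> None:
    """Write fits in the conventional (kcat, Km, kcat/Km, relative %) layout."""
    ref = fits[labels.index(reference_label)]
    with open(path, "w") as fh:
        fh.write("tRNA\tkcat_per_min\tKm_uM\tkcat_over_Km\trelative_pct\n")
        for label, fit in zip(labels, fits):
            fh.write(
                f"{label}\t{fit.kcat:.3g}\t{fit.km:.3g}\t"
                f"{fit.kcat_over_km:.3g}\t{relative_efficiency(fit, ref)}\n"
            )
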