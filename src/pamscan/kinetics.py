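"""Cleavage kinetics from supercoiled-plasmid time courses.

Cas9 cleavage of a supercoiled plasmid is treated as a single-exponential
decay of the supercoiled fraction, SC(t) = exp(-k t) with amplitude fixed at
1 (the substrate starts fully supercoiled).  The rate constant k (per
minute) is estimated by nonlinear least squares seeded with the closed-form
log-linear estimate; replicates are fitted jointly by pooling points.  PAM
variants are compared by the fold change of their rate constants, with a
"no detectable cleavage" sentinel for abolished substrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: sentinel returned when the mutant rate is indistinguishable from zero
ABOLISHED = "abolished"


@dataclass
class KineticsSeries:
    """Supercoiled-fraction measurements for one substrate and replicate."""

    substrate_label: str
    timepoints: np.ndarray
    sc_fraction: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        sc = np.asarray(self.sc_fraction, dtype=float)
        if t.shape != sc.shape or t.ndim != 1:
            raise ValueError("timepoints and sc_fraction must be equal-length 1-D")
        if np.any(t < 0):
            raise ValueError("timepoints must be nonnegative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any((sc < 0) | (sc > 1)):
            raise ValueError("supercoiled fractions must lie in [0, 1]")
        self.timepoints = t
        self.sc_fraction = sc


@dataclass(frozen=True)
class DecayFit:
    """Fitted first-order decay: rate k (1/min), its SE, R^2, points used."""

    k: float
    se: float
    r_squared: float
    n_points: int
    flat: bool = False


def _model(t: np.ndarray, k: float) -> np.ndarray:
    return np.exp(-k * t)


def fit_decay(series: Union[KineticsSeries, Sequence[KineticsSeries]]) -> DecayFit:
    """Least-squares fit of SC(t) = exp(-k t) over one or more replicates.

    The initial estimate is the closed-form through-origin slope of
    ln SC versus t; the bounded fit enforces k >= 0.  A series that never
    leaves SC = 1 yields k = 0 with a warning (no cleavage observed within
    the time course).  Fewer than 3 pooled points is an error.
    """
    if isinstance(series, KineticsSeries):
        series = [series]
    if not series:
        raise ValueError("no series to fit")
    t = np.concatenate([s.timepoints for s in series])
    sc = np.concatenate([s.sc_fraction for s in series])
    n = t.size
    if n < 3:
        raise ValueError(f"need at least 3 points to fit, got {n}")

    if np.all(sc >= 1.0):
        warnings.warn(
            "supercoiled fraction never decays; k = 0 (cleavage slower than "
            "the observation window)", RuntimeWarning, stacklevel=2,
        )
        return DecayFit(k=0.0, se=0.0, r_squared=float("nan"),
                        n_points=n, flat=True)

    # log-linear seed: ln SC = -k t through the origin, positive points only
    mask = (sc > 0) & (t > 0)
    if mask.any():
        k0 = max(0.0, -float(np.sum(t[mask] * np.log(sc[mask]))
                             / np.sum(t[mask] ** 2)))
    else:
        k0 = 1.0 / max(float(t.max()), 1e-9)

    popt, pcov = curve_fit(
        _model, t, sc, p0=[max(k0, 1e-12)], bounds=(0.0, np.inf),
        maxfev=10000,
    )
    k = float(popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("inf")
    resid = sc - _model(t, k)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((sc - sc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return DecayFit(k=k, se=se, r_squared=r2, n_points=n)


def fold_change(
    k_ref: float, k_mut: float, detection_limit: float = 0.0
) -> Union[float, str]:
    """k_ref / k_mut, or the ``ABOLISHED`` sentinel.

    A mutant rate at or below ``detection_limit`` (default: exactly zero) is
    reported as "abolished" rather than an unbounded ratio, matching the
    read-out for a PAM mutation that eliminates cleavage outright.
    """
    if k_ref < 0 or k_mut < 0:
        raise ValueError("rate constants must be nonnegative")
    if k_mut <= detection_limit:
        return ABOLISHED
    return k_ref / k_mut


@dataclass(frozen=True)
class RateComparison:
    substrate: str
    fold: Union[float, str]
    fold_se: float | None


def compare_rates(
    reference: DecayFit, mutant: DecayFit, substrate: str = "",
    sigma: float = 2.0,
) -> RateComparison:
    """Fold change of fitted rates with first-order error propagation.

    A mutant whose fitted rate is within ``sigma`` standard errors of zero is
    reported as abolished (no detectable cleavage).
    """
    limit = sigma * mutant.se if np.isfinite(mutant.se) else 0.0
    fc = fold_change(reference.k, mutant.k, detection_limit=limit)
    if fc == ABOLISHED:
        return RateComparison(substrate, ABOLISHED, None)
    rel = np.sqrt(
        (reference.se / reference.k) ** 2 + (mutant.se / mutant.k) ** 2
    ) if reference.k > 0 and mutant.k > 0 else float("nan")
    return RateComparison(substrate, fc, float(fc * rel))


# -- tabular I/O --------------------------------------------------------------

def read_series_tsv(path) -> list[KineticsSeries]:
    """Load series from TSV columns: substrate, replicate, time_min, sc_fraction."""
    df = pd.read_csv(path, sep="\t")
    out: list[KineticsSeries] = []
    for (label, rep), grp in df.groupby(["substrate", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(KineticsSeries(
            substrate_label=str(label),
            timepoints=grp["time_min"].to_numpy(float),
            sc_fraction=grp["sc_fraction"].to_numpy(float),
            replicate_id=int(rep),
        ))
    return out


def fit_table(
    series: Sequence[KineticsSeries], reference: str | None = None,
    sigma: float = 2.0,
) -> pd.DataFrame:
    """Fit every substrate (replicates pooled); optional fold change vs a reference."""
    groups: dict[str, list[KineticsSeries]] = {}
    for s in series:
        groups.setdefault(s.substrate_label, []).append(s)
    fits = {label: fit_decay(grp) for label, grp in groups.items()}
    rows = []
    ref_fit = fits.get(reference) if reference else None
    for label in sorted(groups):
        f = fits[label]
        row = {
            "substrate": label, "k_per_min": f.k, "k_se": f.se,
            "r_squared": f.r_squared, "n_points": f.n_points,
        }
        if ref_fit is not None:
            cmp = compare_rates(ref_fit, f, substrate=label, sigma=sigma)
            row["fold_vs_reference"] = cmp.fold
            row["fold_se"] = cmp.fold_se
        rows.append(row)
    return pd.DataFrame(rows)
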