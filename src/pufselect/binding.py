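"""Equilibrium binding analysis: one-site fits, replicate SEM, Krel.

An EMSA titration measures bound-RNA signal Y at protein concentration X.
The one-site specific binding model is

    Y = Bmax * X / (Kd + X)

with no nonspecific/baseline term. Replicates are fit independently; the
reported Kd is the mean over replicates with SEM = sd/sqrt(n). Relative
affinity Krel is the ratio of a mean Kd to the mean Kd of a reference RNA
measured under the same protein condition. When the LST-1 partner is held
at constant high concentration, protein concentrations are corrected by a
fixed dilution factor (0.9) before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, InputError
from .reference import PARTNER_DILUTION_FACTOR
from .util import round_sig


@dataclass
class BindingTitration:
    """One replicate titration curve: (concentration nM, signal) points."""

    rna_label: str
    protein_label: str
    partner_present: bool
    replicate_id: int
    concentrations_nM: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_nM = np.asarray(self.concentrations_nM, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.concentrations_nM.shape != self.signals.shape:
            raise InputError("concentration and signal arrays differ in length")
        if np.any(self.concentrations_nM < 0):
            raise InputError("negative concentrations")
        if 0 not in self.concentrations_nM:
            raise InputError("titration must include the protein-free (0 nM) point")


@dataclass
class OneSiteFit:
    """Result of a single-replicate one-site fit."""

    kd: float
    bmax: float
    residuals: np.ndarray
    converged: bool


@dataclass
class BindingFit:
    """Aggregated replicate fits for one RNA under one protein condition."""

    rna_label: str
    protein_label: str
    partner_present: bool
    replicate_kds: list[float]
    replicate_bmaxes: list[float]
    kd_mean: float
    kd_sem: float
    krel: float | None = None
    reference_label: str | None = None


def adjust_concentrations(
    series: Sequence[float], partner_present: bool,
    factor: float = PARTNER_DILUTION_FACTOR,
) -> np.ndarray:
    """Apply the partner-dilution correction to a concentration series."""
    series = np.asarray(series, dtype=float)
    if np.any(series < 0):
        raise InputError("negative concentrations")
    return series * factor if partner_present else series.copy()


def one_site(x: np.ndarray, kd: float, bmax: float) -> np.ndarray:
    """The one-site specific binding curve Bmax*X/(Kd+X)."""
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x)


def fit_one_site(titration: BindingTitration, rel_tol: float = 1e-8) -> OneSiteFit:
    """Least-squares fit of (Kd, Bmax), both constrained positive.

    Positivity is enforced by optimizing in log space. Initialization:
    Kd0 = concentration nearest the half-maximal signal, Bmax0 = maximum
    signal.
    """
    x = titration.concentrations_nM
    y = titration.signals
    if len(np.unique(x)) < 5:
        raise InputError("at least 5 distinct concentrations required for fitting")
    ymax = float(np.max(y))
    if ymax <= 0:
        raise InputError("all signals are zero or negative; nothing to fit")
    nonzero = x[x > 0]
    kd0 = float(nonzero[np.argmin(np.abs(y[x > 0] - ymax / 2))])
    theta0 = np.log([kd0, ymax])

    def resid(theta: np.ndarray) -> np.ndarray:
        kd, bmax = np.exp(theta)
        return one_site(x, kd, bmax) - y

    sol = least_squares(resid, theta0, method="lm", xtol=rel_tol,
                        ftol=rel_tol, gtol=rel_tol, max_nfev=10000)
    kd, bmax = np.exp(sol.x)
    if not sol.success:
        raise FitError(f"one-site fit did not converge: {sol.message}")
    if not (np.isfinite(kd) and np.isfinite(bmax)) or kd > 1e8 * np.max(x):
        raise FitError(f"one-site fit ran away (kd={kd:.3g}, bmax={bmax:.3g})")
    return OneSiteFit(kd=float(kd), bmax=float(bmax),
                      residuals=sol.fun.copy(), converged=True)


def aggregate_replicates(
    fits: Iterable[OneSiteFit | tuple[float, float]]
) -> tuple[float, float]:
    """Mean Kd and SEM (= sd/sqrt(n), sample sd) over replicate fits."""
    kds = [f.kd if isinstance(f, OneSiteFit) else float(f[0]) for f in fits]
    if len(kds) < 2:
        raise InputError("SEM requires at least 2 replicate fits")
    kds = np.asarray(kds, dtype=float)
    return float(kds.mean()), float(kds.std(ddof=1) / np.sqrt(len(kds)))


def fit_replicates(titrations: Sequence[BindingTitration]) -> BindingFit:
    """Fit each replicate independently and aggregate.

    All titrations must share rna_label and protein condition. The
    partner-dilution correction is applied here, before fitting.
    """
    if not titrations:
        raise InputError("no titrations supplied")
    first = titrations[0]
    for t in titrations:
        if (t.rna_label, t.protein_label, t.partner_present) != (
            first.rna_label, first.protein_label, first.partner_present
        ):
            raise InputError("replicates mix RNAs or protein conditions")
    fits = []
    for t in titrations:
        x = adjust_concentrations(t.concentrations_nM, t.partner_present)
        fits.append(fit_one_site(BindingTitration(
            t.rna_label, t.protein_label, t.partner_present,
            t.replicate_id, x, t.signals,
        )))
    kd_mean, kd_sem = aggregate_replicates(fits)
    return BindingFit(
        rna_label=first.rna_label,
        protein_label=first.protein_label,
        partner_present=first.partner_present,
        replicate_kds=[f.kd for f in fits],
        replicate_bmaxes=[f.bmax for f in fits],
        kd_mean=kd_mean,
        kd_sem=kd_sem,
    )


def compute_krel(
    fit: BindingFit, reference: BindingFit, per_replicate: bool = False
) -> float:
    """Relative affinity: Kd of `fit` over Kd of `reference`.

    Both fits must come from the same protein condition. The default uses
    the ratio of mean Kds; ``per_replicate=True`` averages per-replicate
    ratios instead (requires equal replicate counts).
    """
    if fit.partner_present != reference.partner_present:
        raise InputError("Krel requires the same protein condition for both fits")
    if fit.kd_mean <= 0 or reference.kd_mean <= 0:
        raise InputError("Kd means must be positive")
    if per_replicate:
        a, b = fit.replicate_kds, reference.replicate_kds
        if len(a) != len(b):
            raise InputError("per-replicate Krel needs equal replicate counts")
        return float(np.mean(np.asarray(a) / np.asarray(b)))
    return fit.kd_mean / reference.kd_mean


def krel_from_means(kd_mean: float, reference_kd_mean: float) -> float:
    """Krel directly from two mean Kds (e.g. published values)."""
    if kd_mean <= 0 or reference_kd_mean <= 0:
        raise InputError("Kd means must be positive")
    return kd_mean / reference_kd_mean


@dataclass
class ReporterMeasurement:
    """A reporter-assay reading: luminescence normalized to cell density."""

    luminescence: float
    a660: float

    def __post_init__(self) -> None:
        if self.a660 <= 0:
            raise InputError("A660 must be positive")
        if self.luminescence < 0:
            raise InputError("luminescence must be nonnegative")

    @property
    def normalized_activity(self) -> float:
        return self.luminescence / self.a660


def normalize_reporter(m: ReporterMeasurement) -> float:
    """Luminescence / A660: activity per unit of cell density."""
    return m.normalized_activity


def fit_emsa_table(
    titrations: Sequence[BindingTitration],
    reference_rna: str,
) -> pd.DataFrame:
    """Fit every (RNA, condition) group and report Kd, SEM, and Krel.

    Krel is computed within each protein condition against `reference_rna`.
    Kd values are reported to 3 significant figures and Krel to 2, matching
    the conventions of published affinity tables.
    """
    groups: dict[tuple[str, str, bool], list[BindingTitration]] = {}
    for t in titrations:
        groups.setdefault(
            (t.rna_label, t.protein_label, t.partner_present), []
        ).append(t)
    fits = {key: fit_replicates(ts) for key, ts in groups.items()}
    refs = {
        (prot, partner): f
        for (rna, prot, partner), f in fits.items()
        if rna == reference_rna
    }
    rows = []
    for (rna, prot, partner), f in sorted(fits.items()):
        ref = refs.get((prot, partner))
        krel = compute_krel(f, ref) if ref is not None else np.nan
        f.krel = krel
        f.reference_label = reference_rna if ref is not None else None
        rows.append({
            "rna_label": rna,
            "protein_label": prot,
            "partner_present": partner,
            "n_replicates": len(f.replicate_kds),
            "kd_mean_nM": round_sig(f.kd_mean, 3),
            "kd_sem_nM": round_sig(f.kd_sem, 3),
            "krel": round_sig(krel, 2) if np.isfinite(krel) else np.nan,
        })
    return pd.DataFrame(rows)
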