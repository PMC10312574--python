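"""Cooperativity profiling from double-biotin-pair stability measurements.

A point mutation perturbs one residue interaction; measuring the induced
stability change at two different biotin pairs (the N- and C-subdomain
probes) reports how far that perturbation propagates. The statistic

    ΔΔΔG = ΔΔG°_WT-Mut^N − ΔΔG°_WT-Mut^C

is near zero when the mutation destabilizes both subdomains alike
(a cooperative interaction) and large when the effect stays local.
Residues are classified against thermal-energy cutoffs ±RT and ±2RT
(or a narrow scheme ±RT/2 and ±RT).

Environment comparisons (micelle vs bicelle ΔΔG scatter) use
through-origin least squares by default, with slope equality between
groups assessed by Chow's F test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .constants import T_EXPERIMENT, rt
from .thermo import StabilityResult

__all__ = [
    "CLASS_NAMES",
    "CLASS_CODES",
    "MutationRecord",
    "DdgRecord",
    "CooperativityProfile",
    "SlopeComparison",
    "compute_ddg",
    "compute_dddg",
    "classify_cooperativity",
    "fit_slope",
    "chow_test",
    "stratify_by_burial",
    "write_cooperativity_map",
]

CLASS_NAMES = (
    "cooperative",
    "moderately_localized_N",
    "localized_N",
    "moderately_localized_C",
    "localized_C",
)

#: Numeric codes written into PDB B-factors by :func:`write_cooperativity_map`.
CLASS_CODES = {
    "unassigned": 0,
    "cooperative": 1,
    "moderately_localized_N": 2,
    "localized_N": 3,
    "moderately_localized_C": 4,
    "localized_C": 5,
}


@dataclass
class MutationRecord:
    residue_number: int
    wt_aa: str
    mut_aa: str
    f_ASA: float               # fraction of solvent-accessible surface area
    subdomain_location: str    # "N" | "C"

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_ASA <= 1.0:
            raise ValueError(f"f_ASA must lie in [0, 1], got {self.f_ASA}")
        if self.wt_aa == self.mut_aa:
            raise ValueError("mutation must change the residue")


@dataclass
class DdgRecord:
    """Mutation-induced stability changes at both subdomain probes,
    for one environment."""

    mutation: MutationRecord
    environment: str
    ddG_N: float = math.nan
    ddG_C: float = math.nan
    err_N: float = math.nan
    err_C: float = math.nan


@dataclass
class CooperativityProfile:
    """Per-residue ΔΔΔG values and five-way classes under one cutoff scheme."""

    scheme: str                         # "regular" | "narrow"
    dddG: dict[int, float] = field(default_factory=dict)
    classes: dict[int, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"residue": r, "dddG": self.dddG[r],
                 "class": self.classes[r], "scheme": self.scheme}
                for r in sorted(self.dddG)]
        return pd.DataFrame(rows, columns=["residue", "dddG", "class", "scheme"])


@dataclass
class SlopeComparison:
    m1: float
    m1_sd: float
    m2: float
    m2_sd: float
    label1: str
    label2: str
    chow_F: float
    chow_p: float
    tier: str                  # "NS" | "*" | "**"
    k: int                     # regression parameters per group


def compute_ddg(dG_WT: StabilityResult, dG_Mut: StabilityResult) -> tuple[float, float]:
    """ΔΔG°_WT-Mut = ΔG_WT − ΔG_Mut with quadrature error propagation.

    Positive ΔΔG means the mutation destabilized the protein (the mutant
    ΔG is less negative). Both inputs must share subdomain and
    environment tags.
    """
    if dG_WT.subdomain != dG_Mut.subdomain:
        raise ValueError(
            f"subdomain mismatch: {dG_WT.subdomain!r} vs {dG_Mut.subdomain!r}")
    if dG_WT.environment != dG_Mut.environment:
        raise ValueError(
            f"environment mismatch: {dG_WT.environment!r} vs {dG_Mut.environment!r}")
    ddg = dG_WT.dG - dG_Mut.dG
    err = math.hypot(dG_WT.err, dG_Mut.err)
    return ddg, err


def compute_dddg(ddG_N: float, ddG_C: float) -> float:
    """ΔΔΔG = ΔΔG^N − ΔΔG^C (same mutation, same environment)."""
    return ddG_N - ddG_C


def _cutoffs(scheme: str, T: float) -> tuple[float, float]:
    """(inner, outer) cutoff magnitudes for a scheme."""
    RT = rt(T)
    if scheme == "regular":
        return RT, 2.0 * RT
    if scheme == "narrow":
        return 0.5 * RT, RT
    raise ValueError(f"unknown scheme {scheme!r}; expected 'regular' or 'narrow'")


def classify_cooperativity(dddG: float, T: float = T_EXPERIMENT,
                           scheme: str = "regular") -> str:
    """Five-way cooperativity class of a ΔΔΔG value.

    Regular scheme (inner = RT, outer = 2RT; narrow halves both):

    * |ΔΔΔG| ≤ inner                →  cooperative
    * inner < ΔΔΔG ≤ outer          →  moderately_localized_N
    * ΔΔΔG > outer                  →  localized_N
    * −outer ≤ ΔΔΔG < −inner        →  moderately_localized_C
    * ΔΔΔG < −outer                 →  localized_C

    Boundary ties go to the inner (more cooperative) class.
    """
    inner, outer = _cutoffs(scheme, T)
    if abs(dddG) <= inner:
        return "cooperative"
    if dddG > 0:
        return "moderately_localized_N" if dddG <= outer else "localized_N"
    return "moderately_localized_C" if dddG >= -outer else "localized_C"


def _ols(x: np.ndarray, y: np.ndarray, intercept: bool):
    X = sm.add_constant(x) if intercept else x[:, None]
    return sm.OLS(y, X).fit()


def fit_slope(x, y, intercept: bool = False) -> tuple[float, float]:
    """Least-squares slope m and its SD for paired ΔΔG values.

    Default is regression through the origin (a zero ΔΔG in one
    environment should map to zero in the other); pass
    ``intercept=True`` for a free intercept.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need ≥ 3 paired points")
    if np.all(x == 0):
        raise ValueError("all-zero predictor; slope undefined")
    res = _ols(x, y, intercept)
    i = 1 if intercept else 0
    return float(res.params[i]), float(res.bse[i])


def _tier(p: float) -> str:
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def chow_test(group1, group2, intercept: bool = False,
              label1: str = "group1", label2: str = "group2") -> SlopeComparison:
    """Chow's structural-break F test for equal regression coefficients.

    ``group1``/``group2`` are (x, y) pair sequences. With k regression
    parameters per group (1 through-origin, 2 with intercept):

        F = [(SSR_pooled − SSR₁ − SSR₂)/k] / [(SSR₁+SSR₂)/(n₁+n₂−2k)]

    and p comes from F(k, n₁+n₂−2k). Significance tiers: ``*`` p<0.05,
    ``**`` p<0.005, else ``NS``.
    """
    x1, y1 = (np.asarray(a, float) for a in zip(*group1))
    x2, y2 = (np.asarray(a, float) for a in zip(*group2))
    k = 2 if intercept else 1
    n1, n2 = x1.size, x2.size
    if n1 <= k or n2 <= k:
        raise ValueError(f"each group needs more than k={k} points")
    df2 = n1 + n2 - 2 * k
    fit1 = _ols(x1, y1, intercept)
    fit2 = _ols(x2, y2, intercept)
    pooled = _ols(np.concatenate([x1, x2]), np.concatenate([y1, y2]), intercept)
    ssr1, ssr2, ssrp = fit1.ssr, fit2.ssr, pooled.ssr
    F = max(0.0, (ssrp - ssr1 - ssr2) / k) / ((ssr1 + ssr2) / df2)
    p = float(stats.f.sf(F, k, df2))
    i = 1 if intercept else 0
    return SlopeComparison(
        m1=float(fit1.params[i]), m1_sd=float(fit1.bse[i]),
        m2=float(fit2.params[i]), m2_sd=float(fit2.bse[i]),
        label1=label1, label2=label2,
        chow_F=float(F), chow_p=p, tier=_tier(p), k=k)


def stratify_by_burial(records: list[DdgRecord],
                       bins: list[float]) -> dict[str, list[DdgRecord]]:
    """Partition ΔΔG records by the burial (f_ASA) of the mutated residue.

    ``bins`` are sorted thresholds in [0, 1]; a record with f_ASA < first
    threshold falls in the first group, etc. Group labels carry the
    interval. Empty bins produce a warning-bearing empty list, not an
    error.
    """
    if list(bins) != sorted(bins):
        raise ValueError("bins must be sorted")
    edges = [0.0, *bins, 1.0 + 1e-12]
    groups: dict[str, list[DdgRecord]] = {}
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"f_ASA[{lo:g},{min(hi, 1.0):g})"
        labels.append((label, lo, hi))
        groups[label] = []
    for rec in records:
        for label, lo, hi in labels:
            if lo <= rec.mutation.f_ASA < hi:
                groups[label].append(rec)
                break
    return groups


def build_profile(records: list[DdgRecord], T: float = T_EXPERIMENT,
                  scheme: str = "regular") -> CooperativityProfile:
    """Assemble a per-residue ΔΔΔG profile from ΔΔG records."""
    prof = CooperativityProfile(scheme=scheme)
    for rec in records:
        dddg = compute_dddg(rec.ddG_N, rec.ddG_C)
        res = rec.mutation.residue_number
        prof.dddG[res] = dddg
        prof.classes[res] = classify_cooperativity(dddg, T, scheme)
    return prof


def write_cooperativity_map(profile: CooperativityProfile, structure_path,
                            out_path) -> list[int]:
    """Color a structure by cooperativity class via the B-factor column.

    Each residue present in ``profile`` gets its numeric class code
    (:data:`CLASS_CODES`) written into the temperature-factor field of a
    copy of the input PDB; all other residues are coded 0. Residues in
    the profile but absent from the structure are returned (and skipped).
    """
    import biotite.structure.io.pdb as pdb

    pdbfile = pdb.PDBFile.read(str(structure_path))
    structure = pdbfile.get_structure(model=1, extra_fields=["b_factor"])
    codes = np.zeros(structure.array_length())
    polymer = ~structure.hetero     # profile residues are protein residues
    present = set(np.unique(structure.res_id[polymer]).tolist())
    missing = []
    for res, cls in profile.classes.items():
        if res not in present:
            missing.append(res)
            continue
        codes[(structure.res_id == res) & polymer] = CLASS_CODES[cls]
    structure.set_annotation("b_factor", codes)
    out = pdb.PDBFile()
    out.set_structure(structure)
    out.write(str(out_path))
    return missing
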