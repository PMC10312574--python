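"""Trajectory-derived solvation dynamics of amphiphiles on a membrane protein.

The chain of analyses implemented here turns coordinate frames (or
precomputed contact time series) into a solvation free energy:

1. heavy-atom contacts between each amphiphile (lipid or detergent)
   and the protein, at a 5 Å cutoff → contact counts q_i(t);
2. contact events — maximal runs of contact tolerating internal
   non-contacting gaps up to the bulk amphiphile relaxation time
   (default 20 ns);
3. the contact autocorrelation c(τ) = (1/N_c)·Σ_i ⟨q_i(t)·q_i(t+τ)/q_i²(t)⟩_t,
   averaged over events (q is zero once an event has ended, so a
   constant-q event of duration D contributes max(0, 1 − τ/D));
4. the residence time τ_R — the lag at which c(τ) first decays to 1/e
   of its initial value (or, if unreached, solved from a constrained
   triple-exponential fit);
5. the solvation free energy ΔG°_Solv = −RT·ln(τ_R,P·L / τ_R,L·L),
   comparing residence on the protein against residence on other
   amphiphiles in the bulk. Negative values mean the amphiphile
   prefers the protein surface.

Supporting structural operations (Kabsch superposition, RMSD to a
reference, per-residue RMSF, and the lagged conformational RMSD(τ) used
to judge amphiphile equilibration) are included, as is a first-shell
census by molecule type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import R_KCAL, T_SIMULATION

__all__ = [
    "FrameSet",
    "ContactSeries",
    "ContactEvent",
    "AutocorrCurve",
    "ResidenceTime",
    "TripleExpFit",
    "SolvationFreeEnergy",
    "RmsdTauCurve",
    "tail_atom_names",
    "superpose",
    "superposed_rmsd",
    "rmsd_to_reference",
    "rmsf_per_residue",
    "rmsd_tau",
    "detect_contacts",
    "detect_pair_contacts",
    "segment_events",
    "contact_autocorrelation",
    "residence_time",
    "fit_triple_exponential",
    "solvation_free_energy",
    "first_shell_census",
]

MOLECULE_TYPES = ("protein", "lipid", "detergent", "other")


# ---------------------------------------------------------------------------
# containers

@dataclass
class FrameSet:
    """Ordered coordinate frames with a fixed atom roster.

    ``atoms`` columns: ``atom_name``, ``residue_id``, ``molecule_id``,
    ``molecule_type`` (protein|lipid|detergent|other). ``coords`` has
    shape (n_frames, n_atoms, 3) in Å; ``dt`` is the frame spacing in ns.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    dt: float
    box: np.ndarray | None = None   # orthorhombic box lengths, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom roster and coordinate count disagree")
        if self.dt <= 0:
            raise ValueError("frame spacing dt must be positive")
        required = {"atom_name", "residue_id", "molecule_id", "molecule_type"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def heavy_mask(self) -> np.ndarray:
        """Heavy atoms by name convention (honors an ``element`` column)."""
        if "element" in self.atoms.columns:
            return (self.atoms["element"].str.upper() != "H").to_numpy()
        names = self.atoms["atom_name"].str.strip().str.upper()
        return ~names.str.startswith("H").to_numpy()

    def molecule_ids(self, molecule_type: str) -> list:
        sel = self.atoms["molecule_type"] == molecule_type
        return sorted(self.atoms.loc[sel, "molecule_id"].unique())

    def atom_indices(self, molecule_id, heavy_only: bool = True,
                     atom_names: set[str] | None = None) -> np.ndarray:
        mask = (self.atoms["molecule_id"] == molecule_id).to_numpy()
        if heavy_only:
            mask &= self.heavy_mask()
        if atom_names is not None:
            mask &= self.atoms["atom_name"].isin(atom_names).to_numpy()
        return np.flatnonzero(mask)


@dataclass
class ContactSeries:
    """Heavy-atom contact counts q(t) per (amphiphile, partner).

    ``data`` columns: ``time_ns``, ``amphiphile_id``, ``partner``, ``q``.
    The time grid is uniform with spacing ``dt``.
    """

    data: pd.DataFrame
    dt: float

    def __post_init__(self) -> None:
        required = {"time_ns", "amphiphile_id", "partner", "q"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"contact table missing columns: {sorted(missing)}")
        if (self.data["q"] < 0).any():
            raise ValueError("contact counts must be nonnegative")

    def tracks(self):
        """Yield ((amphiphile_id, partner), time array, q array)."""
        for key, grp in self.data.groupby(["amphiphile_id", "partner"],
                                          sort=True):
            grp = grp.sort_values("time_ns")
            yield key, grp["time_ns"].to_numpy(float), grp["q"].to_numpy()


@dataclass
class ContactEvent:
    amphiphile_id: object
    partner: object
    start_ns: float
    end_ns: float            # time of the last contacting frame
    q: np.ndarray            # counts on the frame grid start..end inclusive
    dt: float
    gap_tolerance_ns: float

    @property
    def duration_ns(self) -> float:
        """Event duration counted as (number of frames) · dt."""
        return len(self.q) * self.dt


@dataclass
class AutocorrCurve:
    tau_ns: np.ndarray
    c: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        if self.tau_ns[0] != 0:
            raise ValueError("lag grid must start at 0")


@dataclass
class ResidenceTime:
    tau_R: float             # ns
    method: str              # "one_over_e" | "triple_exp"
    sd: float = 0.0
    extrapolated: bool = False


@dataclass
class TripleExpFit:
    """c(τ) ≈ Σ aₖ·exp(−τ/tₖ) with aₖ ≥ 0, Σaₖ = c(0), t₁ ≤ t₂ ≤ t₃."""

    amplitudes: np.ndarray
    times: np.ndarray
    amplitude_sd: np.ndarray
    time_sd: np.ndarray
    ssr: float

    def __call__(self, tau) -> np.ndarray:
        tau = np.asarray(tau, float)
        return np.sum(self.amplitudes[:, None]
                      * np.exp(-tau[None, :] / self.times[:, None]), axis=0)


@dataclass
class SolvationFreeEnergy:
    dG_solv: float           # kcal/mol
    sd: float
    component: str           # "whole" | "head" | "tail"
    tau_PL: float
    tau_LL: float
    T: float


@dataclass
class RmsdTauCurve:
    tau_ns: np.ndarray
    rmsd: np.ndarray         # Å, averaged over molecules then over t
    n_molecules: int


# ---------------------------------------------------------------------------
# selections

def tail_atom_names(kind: str) -> set[str]:
    """Tail heavy-atom names for an amphiphile kind ("dmpc" or "ddm").

    Shipped as editable text files; DMPC tails are the two aliphatic
    chains C22–C214 and C32–C314, the DDM tail is the dodecyl chain
    C1–C12. Everything else in the molecule is head group.
    """
    fname = {"dmpc": "dmpc_tail_atoms.txt", "ddm": "ddm_tail_atoms.txt"}.get(
        kind.lower())
    if fname is None:
        raise ValueError(f"unknown amphiphile kind {kind!r}")
    text = resources.files("sterictrap.data").joinpath(fname).read_text()
    return {line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")}


def head_tail_indices(frames: FrameSet, molecule_id,
                      kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom index arrays (head, tail) for one amphiphile.

    The union is all heavy atoms of the molecule and the intersection is
    empty: tail atoms are the named chain carbons, head is the rest.
    """
    tails = tail_atom_names(kind)
    all_idx = frames.atom_indices(molecule_id, heavy_only=True)
    names = frames.atoms["atom_name"].to_numpy()
    tail_idx = np.array([i for i in all_idx if names[i] in tails], dtype=int)
    head_idx = np.array([i for i in all_idx if names[i] not in tails], dtype=int)
    return head_idx, tail_idx


# ---------------------------------------------------------------------------
# superposition and fluctuation analysis

def superpose(ref_coords, mov_coords):
    """Optimal rigid (Kabsch) superposition of ``mov`` onto ``ref``.

    Returns ``(rotation_matrix, translation, rmsd)`` such that
    ``mov @ R.T + t`` best fits ``ref`` in the least-squares sense; the
    rotation is proper (det = +1) and ``rmsd`` is the post-alignment
    RMSD in Å.
    """
    ref = np.asarray(ref_coords, float)
    mov = np.asarray(mov_coords, float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[0] < 3:
        raise ValueError("need two equal (n ≥ 3, 3) coordinate arrays")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    a = ref - ref_c
    b = mov - mov_c
    if np.linalg.matrix_rank(np.vstack([a, b])) < 2:
        raise ValueError("degenerate (collinear) geometry")
    rot, _ = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    diff = a - b @ R.T
    rmsd = math.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    t = ref_c - mov_c @ R.T
    return R, t, float(rmsd)


def superposed_rmsd(ref_coords, mov_coords) -> float:
    """Post-alignment RMSD between two conformations, Å."""
    return superpose(ref_coords, mov_coords)[2]


def rmsd_to_reference(frames: FrameSet, selection: np.ndarray,
                      reference: np.ndarray) -> np.ndarray:
    """Per-frame superposed RMSD of selected atoms to a reference, Å."""
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    ref = np.asarray(reference, float)
    if ref.shape != (selection.size, 3):
        raise ValueError("reference does not match selection roster")
    return np.array([superposed_rmsd(ref, self_coords)
                     for self_coords in frames.coords[:, selection, :]])


def rmsf_per_residue(frames: FrameSet, selection: np.ndarray | None = None,
                     align: bool = True) -> pd.Series:
    """Per-residue RMSF after superposing all frames to their mean, Å.

    Frames are aligned to the raw mean structure, the mean is recomputed
    once, and RMSF = √⟨|r − ⟨r⟩|²⟩ per atom is averaged over each
    residue's selected atoms. ``align=False`` skips superposition.
    """
    if frames.n_frames < 2:
        raise ValueError("need ≥ 2 frames for fluctuations")
    if selection is None:
        selection = np.flatnonzero(frames.heavy_mask())
    selection = np.asarray(selection, int)
    X = frames.coords[:, selection, :].copy()
    if align:
        for _ in range(2):   # align to mean, recompute mean, realign once
            mean = X.mean(axis=0)
            for f in range(X.shape[0]):
                R, t, _ = superpose(mean, X[f])
                X[f] = X[f] @ R.T + t
    mean = X.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    res_ids = frames.atoms["residue_id"].to_numpy()[selection]
    return pd.Series(per_atom).groupby(res_ids).mean().rename("rmsf_A")


def rmsd_tau(frames: FrameSet, bulk_molecules, max_lag_ns: float,
             t_stride: int = 1) -> RmsdTauCurve:
    """Lagged conformational RMSD of bulk amphiphiles (equilibration check).

    For each lag τ, the heavy-atom RMSD between one molecule's
    conformations at t and t+τ (superposed pairwise) is averaged over
    all valid t, then molecules are averaged with equal weight. The
    plateau onset of this curve is the bulk conformational relaxation
    time used as the contact-event gap tolerance.
    """
    if not len(bulk_molecules):
        raise ValueError("no bulk molecules given")
    n_lag = int(round(max_lag_ns / frames.dt))
    if n_lag >= frames.n_frames:
        n_lag = frames.n_frames - 1
    lags = np.arange(n_lag + 1)
    per_mol = np.zeros((len(bulk_molecules), lags.size))
    for m, mol in enumerate(bulk_molecules):
        idx = frames.atom_indices(mol, heavy_only=True)
        X = frames.coords[:, idx, :]
        for j, lag in enumerate(lags):
            if lag == 0:
                continue
            ts = range(0, frames.n_frames - lag, t_stride)
            per_mol[m, j] = np.mean([superposed_rmsd(X[t], X[t + lag])
                                     for t in ts])
    return RmsdTauCurve(tau_ns=lags * frames.dt,
                        rmsd=per_mol.mean(axis=0),
                        n_molecules=len(bulk_molecules))


# ---------------------------------------------------------------------------
# contacts

def _counts_vs_tree(coords: np.ndarray, idx: np.ndarray,
                    tree: cKDTree, cutoff: float) -> int:
    if idx.size == 0:
        return 0
    hits = tree.query_ball_point(coords[idx], r=cutoff)
    return int(sum(1 for h in hits if h))


def detect_contacts(frames: FrameSet, cutoff: float = 5.0,
                    amphiphile_ids=None,
                    atom_names: set[str] | None = None) -> ContactSeries:
    """Heavy-atom contact counts of each amphiphile with the protein.

    q_i(t) is the number of heavy atoms of amphiphile i within
    ``cutoff`` Å of any protein heavy atom in frame t. ``atom_names``
    restricts the amphiphile side to a subset (e.g. head or tail
    atoms); the protein side always uses all heavy atoms.
    """
    heavy = frames.heavy_mask()
    prot = np.flatnonzero((frames.atoms["molecule_type"] == "protein").to_numpy()
                          & heavy)
    if prot.size == 0:
        raise ValueError("no protein heavy atoms in FrameSet")
    if amphiphile_ids is None:
        amphiphile_ids = [m for t in ("lipid", "detergent")
                          for m in frames.molecule_ids(t)]
    mol_idx = {mol: frames.atom_indices(mol, heavy_only=True,
                                        atom_names=atom_names)
               for mol in amphiphile_ids}
    rows = []
    for f in range(frames.n_frames):
        tree = cKDTree(frames.coords[f, prot, :])
        t_ns = f * frames.dt
        for mol in amphiphile_ids:
            q = _counts_vs_tree(frames.coords[f], mol_idx[mol], tree, cutoff)
            rows.append((t_ns, mol, "protein", q))
    return ContactSeries(
        data=pd.DataFrame(rows, columns=["time_ns", "amphiphile_id",
                                         "partner", "q"]),
        dt=frames.dt)


def detect_pair_contacts(frames: FrameSet, pairs, cutoff: float = 5.0,
                         atom_names: set[str] | None = None) -> ContactSeries:
    """Contact counts between amphiphile pairs (the bulk L·L reference).

    ``pairs`` is a sequence of (amphiphile_id, partner_id); q is the
    number of heavy atoms of the first molecule within ``cutoff`` of any
    heavy atom of the second.
    """
    rows = []
    for f in range(frames.n_frames):
        t_ns = f * frames.dt
        for mol, partner in pairs:
            idx = frames.atom_indices(mol, heavy_only=True,
                                      atom_names=atom_names)
            pidx = frames.atom_indices(partner, heavy_only=True)
            tree = cKDTree(frames.coords[f, pidx, :])
            q = _counts_vs_tree(frames.coords[f], idx, tree, cutoff)
            rows.append((t_ns, mol, partner, q))
    return ContactSeries(
        data=pd.DataFrame(rows, columns=["time_ns", "amphiphile_id",
                                         "partner", "q"]),
        dt=frames.dt)


def segment_events(series: ContactSeries,
                   gap_tolerance_ns: float = 20.0) -> list[ContactEvent]:
    """Split contact tracks into events, merging short non-contact gaps.

    An event is a maximal run of q > 0 whose internal zero-gaps are all
    ≤ ``gap_tolerance_ns`` (the bulk amphiphile relaxation time); events
    are trimmed to their first and last contacting frames.
    """
    max_gap_frames = int(math.floor(gap_tolerance_ns / series.dt + 1e-9))
    events: list[ContactEvent] = []
    for (mol, partner), times, q in series.tracks():
        nz = np.flatnonzero(q > 0)
        if nz.size == 0:
            continue
        start = prev = nz[0]
        for i in nz[1:]:
            if i - prev - 1 > max_gap_frames:
                events.append(ContactEvent(
                    mol, partner, times[start], times[prev],
                    q[start:prev + 1].copy(), series.dt, gap_tolerance_ns))
                start = i
            prev = i
        events.append(ContactEvent(
            mol, partner, times[start], times[prev],
            q[start:prev + 1].copy(), series.dt, gap_tolerance_ns))
    return events


def contact_autocorrelation(events: list[ContactEvent],
                            max_lag_ns: float,
                            symmetric: bool = False) -> AutocorrCurve:
    """Event-averaged contact autocorrelation c(τ).

    c(τ) = (1/N_c)·Σ_i ⟨q_i(t)·q_i(t+τ)/q_i²(t)⟩_t with the asymmetric
    normalization as the default; the time average runs over event
    frames with q_i(t) > 0, and q_i is zero once the event has ended,
    so a constant-q event of duration D contributes max(0, 1 − τ/D).
    c(0) = 1 exactly. ``symmetric=True`` normalizes by q(t)·q(t+τ)'s
    geometric pairing ⟨q(t)q(t+τ)⟩/⟨q²⟩ instead (non-default).
    """
    if not events:
        raise ValueError("no contact events")
    dt = events[0].dt
    n_lag = int(round(max_lag_ns / dt))
    lags = np.arange(n_lag + 1)
    acc = np.zeros(lags.size)
    for ev in events:
        q = np.asarray(ev.q, float)
        n = q.size
        valid = q > 0
        denom = int(valid.sum())
        ci = np.zeros(lags.size)
        for j, lag in enumerate(lags):
            qlag = np.zeros(n)
            if lag < n:
                qlag[:n - lag] = q[lag:]
            # beyond the event end q is 0 (the contact no longer exists)
            if symmetric:
                num = float(np.sum(q[valid] * qlag[valid]))
                den = float(np.sum(q[valid] ** 2))
                ci[j] = num / den
            else:
                ci[j] = float(np.mean(qlag[valid] / q[valid]))
        acc += ci
    c = acc / len(events)
    c[0] = 1.0
    return AutocorrCurve(tau_ns=lags * dt, c=c, n_events=len(events))


def residence_time(curve: AutocorrCurve,
                   method: str = "one_over_e") -> ResidenceTime:
    """Residence time: lag at which c(τ) decays to 1/e of c(0).

    ``one_over_e`` takes the first downward crossing of c(0)/e with
    linear interpolation between lag samples; if the curve never
    crosses, a triple-exponential fit is solved instead and the result
    flagged as extrapolated. ``triple_exp`` always uses the fit and
    carries a delta-method SD from the fit covariance.
    """
    c0 = curve.c[0]
    if c0 <= 0:
        raise ValueError("c(0) must be positive")
    target = c0 / math.e
    if np.all(np.diff(curve.c) >= 0) and curve.c.size > 1:
        raise ValueError("autocorrelation is monotone increasing; no decay")
    if method == "one_over_e":
        below = np.flatnonzero(curve.c < target)
        if below.size:
            j = below[0]
            if j == 0:
                return ResidenceTime(tau_R=float(curve.tau_ns[0]),
                                     method="one_over_e")
            t0, t1 = curve.tau_ns[j - 1], curve.tau_ns[j]
            c_hi, c_lo = curve.c[j - 1], curve.c[j]
            tau = t0 + (c_hi - target) / (c_hi - c_lo) * (t1 - t0)
            return ResidenceTime(tau_R=float(tau), method="one_over_e")
        method_result = _tau_from_triple_exp(curve, target)
        method_result.extrapolated = True
        return method_result
    if method == "triple_exp":
        return _tau_from_triple_exp(curve, target)
    raise ValueError(f"unknown method {method!r}")


def _tau_from_triple_exp(curve: AutocorrCurve, target: float) -> ResidenceTime:
    fit = fit_triple_exponential(curve)

    def decay(tau):
        return float(np.sum(fit.amplitudes * np.exp(-tau / fit.times))) - target

    hi = 10.0 * fit.times.max()
    while decay(hi) > 0 and hi < 1e9:
        hi *= 10.0
    tau = brentq(decay, 0.0, hi)
    # implicit-function delta method: dτ/dθ = −(∂f/∂θ)/(∂f/∂τ)
    dfdtau = float(np.sum(-fit.amplitudes / fit.times * np.exp(-tau / fit.times)))
    var = 0.0
    for k in range(3):
        e = math.exp(-tau / fit.times[k])
        dfda = e
        dfdt = fit.amplitudes[k] * e * tau / fit.times[k] ** 2
        var += (dfda * fit.amplitude_sd[k] / dfdtau) ** 2
        var += (dfdt * fit.time_sd[k] / dfdtau) ** 2
    return ResidenceTime(tau_R=float(tau), method="triple_exp",
                         sd=math.sqrt(var))


def fit_triple_exponential(curve: AutocorrCurve) -> TripleExpFit:
    """Constrained triple-exponential fit of an autocorrelation curve.

    Amplitudes are nonnegative and sum to c(0) (stick-breaking
    parameterization); decay times are fitted on a log scale from a
    deterministic multi-start grid of log-spaced triples. SDs come from
    the least-squares covariance mapped through the parameterization.
    """
    tau = np.asarray(curve.tau_ns, float)
    c = np.asarray(curve.c, float)
    if tau.size < 7:
        raise ValueError("need ≥ 7 lag points for a triple exponential")
    c0 = c[0]
    span = max(tau[-1], tau[1] if tau.size > 1 else 1.0)

    def unpack(p):
        s1, s2, lt1, lt2, lt3 = p
        a = np.array([s1, (1 - s1) * s2, (1 - s1) * (1 - s2)]) * c0
        t = np.exp(np.array([lt1, lt2, lt3]))
        return a, t

    def resid(p):
        a, t = unpack(p)
        return np.sum(a[:, None] * np.exp(-tau[None, :] / t[:, None]),
                      axis=0) - c

    lt_lo = math.log(max(span * 1e-4, 1e-12))
    lt_hi = math.log(span * 1e3)
    grid = np.log(np.array([span * 0.01, span * 0.1, span, span * 10.0]))
    best = None
    for i in range(len(grid)):
        for j in range(i, len(grid)):
            for k in range(j, len(grid)):
                p0 = np.array([1 / 3, 1 / 2, grid[i], grid[j], grid[k]])
                p0[2:] = np.clip(p0[2:], lt_lo + 1e-6, lt_hi - 1e-6)
                res = least_squares(
                    resid, p0,
                    bounds=([0, 0, lt_lo, lt_lo, lt_lo],
                            [1, 1, lt_hi, lt_hi, lt_hi]))
                if best is None or res.cost < best.cost:
                    best = res
    if best is None or not best.success:
        raise RuntimeError("triple-exponential fit did not converge")

    a, t = unpack(best.x)
    ssr = 2.0 * best.cost
    dof = max(tau.size - 5, 1)
    try:
        cov_p = np.linalg.pinv(best.jac.T @ best.jac) * ssr / dof
    except np.linalg.LinAlgError:
        cov_p = np.zeros((5, 5))
    # numerical delta method p -> (a, t)
    J = np.zeros((6, 5))
    h = 1e-6
    for m in range(5):
        p_hi = best.x.copy()
        p_lo = best.x.copy()
        p_hi[m] += h
        p_lo[m] -= h
        a_hi, t_hi = unpack(p_hi)
        a_lo, t_lo = unpack(p_lo)
        J[:3, m] = (a_hi - a_lo) / (2 * h)
        J[3:, m] = (t_hi - t_lo) / (2 * h)
    cov_at = J @ cov_p @ J.T
    sd = np.sqrt(np.maximum(np.diag(cov_at), 0.0))
    order = np.argsort(t)
    a, t = a[order], t[order]
    a_sd, t_sd = sd[:3][order], sd[3:][order]
    # degenerate components (equal decay times) split the amplitude
    # arbitrarily; merge them into a canonical single component
    for k in range(2):
        if t[k + 1] <= t[k] * 1.01:
            a[k + 1] += a[k]
            a_sd[k + 1] = math.hypot(a_sd[k + 1], a_sd[k])
            a[k], a_sd[k] = 0.0, 0.0
    return TripleExpFit(amplitudes=a, times=t,
                        amplitude_sd=a_sd, time_sd=t_sd, ssr=float(ssr))


# ---------------------------------------------------------------------------
# free energy and census

def solvation_free_energy(tau_PL: float, tau_LL: float,
                          T: float = T_SIMULATION,
                          sd_PL: float = 0.0, sd_LL: float = 0.0,
                          component: str = "whole") -> SolvationFreeEnergy:
    """Solvation free energy from the residence-time ratio.

    ΔG°_Solv = −R·T·ln(τ_R,P·L / τ_R,L·L), kcal/mol. The off-rates of
    an amphiphile from the protein and from a bulk amphiphile partner
    are the inverse residence times, so the ratio is the solvation
    equilibrium constant. Negative values mean the amphiphile favors
    the protein's first solvation shell over the bulk amphiphile phase.
    Input SDs propagate by the delta method.
    """
    if tau_PL <= 0 or tau_LL <= 0:
        raise ValueError("residence times must be positive")
    dG = -R_KCAL * T * math.log(tau_PL / tau_LL)
    sd = R_KCAL * T * math.hypot(sd_PL / tau_PL, sd_LL / tau_LL)
    return SolvationFreeEnergy(dG_solv=dG, sd=sd, component=component,
                               tau_PL=tau_PL, tau_LL=tau_LL, T=T)


def first_shell_census(frames: FrameSet, cutoff: float = 5.0):
    """Amphiphiles in the protein's first solvation shell, per frame.

    An amphiphile is in-shell in a frame iff it has at least one heavy
    atom within ``cutoff`` Å of a protein heavy atom (q ≥ 1). Returns a
    per-frame count table by molecule type, the time averages, and the
    per-frame membership lists.
    """
    series = detect_contacts(frames, cutoff=cutoff)
    mol_type = dict(zip(frames.atoms["molecule_id"],
                        frames.atoms["molecule_type"]))
    members: dict[float, list] = {}
    rows = []
    for t_ns, grp in series.data.groupby("time_ns"):
        in_shell = grp.loc[grp["q"] >= 1, "amphiphile_id"].tolist()
        members[float(t_ns)] = in_shell
        counts = {"time_ns": float(t_ns), "lipid": 0, "detergent": 0, "other": 0}
        for mol in in_shell:
            counts[mol_type[mol]] += 1
        rows.append(counts)
    table = pd.DataFrame(rows).sort_values("time_ns").reset_index(drop=True)
    means = table[["lipid", "detergent", "other"]].mean().to_dict()
    return table, means, members
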