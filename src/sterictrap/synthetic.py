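"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure one estimator
assumes — noisy steric-trap isotherms, mutant ΔΔG tables with planted
cooperativity classes and environment slopes, telegraph-like contact
time series with known event-duration laws, and toy coordinate frames
with planted first-shell geometry and conformational jitter — and
returns a machine-readable truth record alongside the dataset. All
randomness flows through one integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .constants import T_EXPERIMENT, rt
from .cooperativity import DdgRecord, MutationRecord, classify_cooperativity
from .solvation import ContactSeries, FrameSet
from .thermo import (BindingParams, IsothermDataset, KD_from_dg, apparent_kd,
                     steric_trap_signal)

__all__ = [
    "gen_isotherm",
    "gen_mutation_table",
    "gen_contact_series",
    "gen_frames",
]


def gen_isotherm(seed: int, dG_true: float = -7.0,
                 K_d_biotin: float = 52e-12,
                 F_o: float = 1.0, F_inf: float = 0.0,
                 n_replicates: int = 3, n_points: int = 12,
                 noise_frac: float = 0.02,
                 T: float = T_EXPERIMENT) -> tuple[IsothermDataset, dict]:
    """Noisy steric-trap (second binding phase) titration.

    The titrant grid is log-spaced from K_app/100 to 100·K_app so the
    attenuated transition is fully bracketed; each replicate gets iid
    Gaussian noise with σ = ``noise_frac``·|F_inf − F_o| (plate-reader
    like). Defaults mirror the experimental conditions: ΔG°_N-D of
    −7 kcal/mol, the 52 pM biotin affinity of the weak mSA variant,
    pyrene quenching from F_o = 1 to F_inf = 0, 2% noise, triplicates.
    """
    if dG_true >= 0:
        raise ValueError("dG_true must be negative (stable native state)")
    rng = np.random.default_rng(seed)
    K_D = KD_from_dg(dG_true, T)
    params = BindingParams(K_d_biotin=K_d_biotin, K_D=K_D, F_o=F_o, F_inf=F_inf)
    K_app = apparent_kd(K_d_biotin, K_D)
    conc = np.logspace(math.log10(K_app / 100.0), math.log10(K_app * 100.0),
                       n_points)
    sigma = noise_frac * abs(F_inf - F_o)
    chunks = []
    for rep in range(n_replicates):
        signal = steric_trap_signal(params, conc)
        signal = signal + rng.normal(0.0, sigma, size=conc.size)
        chunks.append(pd.DataFrame({"conc_M": conc, "signal": signal,
                                    "replicate": rep}))
    data = IsothermDataset(data=pd.concat(chunks, ignore_index=True),
                           meta={"model": "steric_trap", "seed": seed})
    truth = {"dG_true": dG_true, "K_D": K_D, "K_d_biotin": K_d_biotin,
             "K_app": K_app, "F_o": F_o, "F_inf": F_inf,
             "noise_sd": sigma, "n_replicates": n_replicates, "T": T,
             "seed": seed}
    return data, truth


_DDDG_BANDS = {
    # target ΔΔΔG band per class (regular scheme, in RT units)
    "cooperative": (-1.0, 1.0),
    "moderately_localized_N": (1.0, 2.0),
    "localized_N": (2.0, 4.0),
    "moderately_localized_C": (-2.0, -1.0),
    "localized_C": (-4.0, -2.0),
}

_AA = "ACDEFGHIKLMNPQRSTVWY"


def gen_mutation_table(seed: int, n_residues: int = 37,
                       classes: list[str] | None = None,
                       m_true: float = 1.3, noise_sd: float = 0.1,
                       band_margin: float = 0.0,
                       T: float = T_EXPERIMENT
                       ) -> tuple[dict[str, list[DdgRecord]], dict]:
    """Mutant ΔΔG tables with planted cooperativity structure.

    For each residue a target ΔΔΔG is drawn uniformly inside the band
    of its intended class (shrunk by ``band_margin`` kcal/mol on each
    side); micelle ΔΔG_C is drawn in a destabilizing range and ΔΔG_N
    set to hit the target. Bicelle values are m_true·micelle + noise,
    emulating the environment-slope structure. Gaussian noise of SD
    ``noise_sd`` is added to every measured ΔΔG. Defaults follow the
    experimental design: 37 mutated residues, a C-subdomain
    bicelle/micelle slope of 1.3, ~0.1 kcal/mol measurement noise.

    Returns ``{"micelle": [...], "bicelle": [...]}`` and the truth record.
    """
    rng = np.random.default_rng(seed)
    RT = rt(T)
    if classes is None:
        classes = list(rng.choice(list(_DDDG_BANDS), size=n_residues))
    else:
        n_residues = len(classes)
    residues = np.arange(100, 100 + n_residues)
    records: dict[str, list[DdgRecord]] = {"micelle": [], "bicelle": []}
    truth_rows = []
    for res, cls in zip(residues, classes):
        lo, hi = _DDDG_BANDS[cls]
        lo_k, hi_k = lo * RT + band_margin, hi * RT - band_margin
        if hi_k <= lo_k:
            raise ValueError(
                f"band_margin {band_margin} exceeds half the {cls} band width")
        dddg = float(rng.uniform(lo_k, hi_k))
        ddg_C = float(rng.uniform(0.5, 2.5))
        ddg_N = ddg_C + dddg
        wt = _AA[rng.integers(len(_AA))]
        mut = "A" if wt != "A" else "G"
        mrec = MutationRecord(residue_number=int(res), wt_aa=wt, mut_aa=mut,
                              f_ASA=float(rng.uniform(0.0, 0.6)),
                              subdomain_location="N" if rng.random() < 0.5 else "C")
        for env, scale in (("micelle", 1.0), ("bicelle", m_true)):
            records[env].append(DdgRecord(
                mutation=mrec, environment=env,
                ddG_N=scale * ddg_N + float(rng.normal(0, noise_sd)),
                ddG_C=scale * ddg_C + float(rng.normal(0, noise_sd)),
                err_N=noise_sd, err_C=noise_sd))
        truth_rows.append({"residue": int(res), "class": cls,
                           "dddG_micelle": dddg, "ddG_N": ddg_N,
                           "ddG_C": ddg_C})
    truth = {"m_true": m_true, "noise_sd": noise_sd, "T": T, "seed": seed,
             "residues": truth_rows}
    return records, truth


def gen_contact_series(seed: int, n_events: int = 500,
                       duration_law: str = "fixed",
                       duration_ns: float = 10.0,
                       gap_mean_ns: float = 100.0,
                       gap_tolerance_ns: float = 20.0,
                       q_mode: str = "constant", q0: int = 5,
                       dt: float = 0.5,
                       events_per_track: int = 10
                       ) -> tuple[ContactSeries, dict]:
    """Telegraph-like contact time series with known event statistics.

    Events have fixed duration D (``duration_law="fixed"``) or
    exponential durations of mean D (``"exponential"``); inter-event
    gaps are ``gap_tolerance + dt`` plus an exponential of mean
    ``gap_mean_ns`` so segmentation at the stated tolerance recovers
    the planted events one-for-one. Within an event q is either
    constant q0 or 1 + Poisson(q0 − 1). Durations are rounded to whole
    frames with duration = n_frames·dt.
    """
    rng = np.random.default_rng(seed)
    if dt > duration_ns:
        import warnings
        warnings.warn("frame spacing exceeds the mean event duration")
    rows = []
    durations = []
    ev = 0
    track = 0
    while ev < n_events:
        q_track: list[int] = []
        for _ in range(min(events_per_track, n_events - ev)):
            gap = gap_tolerance_ns + dt + float(rng.exponential(gap_mean_ns))
            q_track.extend([0] * int(round(gap / dt)))
            if duration_law == "fixed":
                D = duration_ns
            elif duration_law == "exponential":
                D = float(rng.exponential(duration_ns))
            else:
                raise ValueError(f"unknown duration law {duration_law!r}")
            n_frames = max(1, int(round(D / dt)))
            durations.append(n_frames * dt)
            if q_mode == "constant":
                qs = [q0] * n_frames
            elif q_mode == "poisson":
                qs = (1 + rng.poisson(max(q0 - 1, 0), size=n_frames)).tolist()
            else:
                raise ValueError(f"unknown q mode {q_mode!r}")
            q_track.extend(qs)
            ev += 1
        q_track.extend([0] * int(round((gap_tolerance_ns + dt) / dt)))
        times = np.arange(len(q_track)) * dt
        rows.append(pd.DataFrame({"time_ns": times,
                                  "amphiphile_id": f"A{track}",
                                  "partner": "protein",
                                  "q": q_track}))
        track += 1
    series = ContactSeries(data=pd.concat(rows, ignore_index=True), dt=dt)
    truth = {"n_events": n_events, "duration_law": duration_law,
             "duration_ns": duration_ns, "mean_duration_ns": float(np.mean(durations)),
             "gap_tolerance_ns": gap_tolerance_ns, "q_mode": q_mode,
             "q0": q0, "dt": dt, "seed": seed}
    return series, truth


def _blob(rng, n, radius, min_sep=0.8, center=(0.0, 0.0, 0.0)):
    """Random points in a sphere with a minimum separation."""
    pts = []
    attempts = 0
    while len(pts) < n:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep:
            attempts += 1
            if attempts > 10000:
                raise RuntimeError("could not place non-overlapping atoms")
            continue
        pts.append(p)
    return np.array(pts) + np.asarray(center)


def gen_frames(seed: int, n_frames: int = 10, dt: float = 0.5,
               n_protein_atoms: int = 40,
               n_in_shell: int = 3, n_bulk: int = 2,
               atoms_per_amphiphile: int = 8,
               amphiphile_type: str = "lipid",
               contact_distance: float = 3.5,
               bulk_distance: float = 30.0,
               jitter_sd: float = 0.0) -> tuple[FrameSet, dict]:
    """Toy multi-frame coordinates with planted contact geometry.

    A protein blob sits at the origin; ``n_in_shell`` amphiphiles have
    their first atom placed ``contact_distance`` Å from a protein
    surface atom (inside the 5 Å shell), the rest are parked
    ``bulk_distance`` Å away. Every frame adds iid Gaussian jitter with
    an RMS 3-D displacement of ``jitter_sd`` Å per atom (per-coordinate
    SD jitter_sd/√3), so in-shell membership and conformational noise
    are known exactly; the pairwise lagged RMSD of a jittered-static
    molecule plateaus near √2·jitter_sd.
    """
    rng = np.random.default_rng(seed)
    prot = _blob(rng, n_protein_atoms, radius=8.0)
    surface = prot[np.argmax(np.linalg.norm(prot, axis=1))]
    outward = surface / np.linalg.norm(surface)

    names, res_ids, mol_ids, mol_types = [], [], [], []
    base = [prot]
    for i in range(n_protein_atoms):
        names.append("CA")
        res_ids.append(i + 1)
        mol_ids.append("PROT")
        mol_types.append("protein")

    n_amph = n_in_shell + n_bulk
    in_shell_ids = []
    for a in range(n_amph):
        if a < n_in_shell:
            anchor = surface + outward * contact_distance
            in_shell_ids.append(f"L{a}")
        else:
            angle = 2 * math.pi * a / max(n_amph, 1)
            anchor = np.array([math.cos(angle), math.sin(angle), 0.0]) \
                * bulk_distance
        chain = anchor + np.cumsum(
            np.vstack([np.zeros(3),
                       rng.normal(0, 0.4, size=(atoms_per_amphiphile - 1, 3))
                       + outward * 1.2]), axis=0)
        base.append(chain)
        for k in range(atoms_per_amphiphile):
            names.append(f"C{k + 1}")
            res_ids.append(1000 + a)
            mol_ids.append(f"L{a}")
            mol_types.append(amphiphile_type)

    base_coords = np.vstack(base)
    coords = np.repeat(base_coords[None, :, :], n_frames, axis=0)
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd / math.sqrt(3.0),
                                     size=coords.shape)
    atoms = pd.DataFrame({"atom_name": names, "residue_id": res_ids,
                          "molecule_id": mol_ids, "molecule_type": mol_types})
    frames = FrameSet(atoms=atoms, coords=coords, dt=dt)
    truth = {"in_shell": in_shell_ids, "n_in_shell": n_in_shell,
             "n_bulk": n_bulk, "jitter_sd": jitter_sd, "dt": dt,
             "contact_distance": contact_distance, "seed": seed}
    return frames, truth
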