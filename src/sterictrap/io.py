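"""Readers and writers for the pipeline's text formats.

Formats are deliberately plain: CSV for titrations, TSV for stability /
ΔΔG / profile / contact / autocorrelation tables, JSON for fit reports
and solvation results, and multi-model PDB (with a chain→type sidecar
TSV) for coordinate frames. Readers validate and reject malformed input
rather than coercing it; every writer's output is parseable by its
paired reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cooperativity import CooperativityProfile, DdgRecord, MutationRecord
from .solvation import AutocorrCurve, ContactSeries, FrameSet
from .thermo import FitResult, IsothermDataset, StabilityResult

__all__ = [
    "UNIT_FACTORS",
    "read_titration_csv",
    "write_titration_csv",
    "write_fit_report",
    "write_stability_table",
    "read_stability_table",
    "write_ddg_table",
    "read_ddg_table",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_contact_series",
    "read_contact_series",
    "write_autocorr_tsv",
    "read_autocorr_tsv",
    "write_frames_pdb",
    "read_frames_pdb",
    "write_json",
]

UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
                "nM": 1e-9, "pM": 1e-12}


def read_titration_csv(path, conc_unit: str | None = None) -> IsothermDataset:
    """Read a titration CSV with header ``conc_M,signal,replicate``.

    A ``conc_unit`` column (or the ``conc_unit`` argument) rescales the
    concentration column into molar; without either, concentrations are
    taken as already molar. Malformed rows raise with line numbers.
    """
    df = pd.read_csv(path)
    for col in ("conc_M", "signal", "replicate"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = df[df[["conc_M", "signal"]].isna().any(axis=1)]
    if len(bad):
        lines = (bad.index + 2).tolist()   # header is line 1
        raise ValueError(f"{path}: unparseable rows at lines {lines}")
    if "conc_unit" in df.columns:
        factors = df["conc_unit"].map(UNIT_FACTORS)
        if factors.isna().any():
            unknown = sorted(df.loc[factors.isna(), "conc_unit"].unique())
            raise ValueError(f"{path}: unknown concentration units {unknown}")
        df["conc_M"] = df["conc_M"] * factors
        df = df.drop(columns=["conc_unit"])
    elif conc_unit is not None:
        if conc_unit not in UNIT_FACTORS:
            raise ValueError(f"unknown concentration unit {conc_unit!r}")
        df["conc_M"] = df["conc_M"] * UNIT_FACTORS[conc_unit]
    df["replicate"] = df["replicate"].astype(int)
    return IsothermDataset(data=df[["conc_M", "signal", "replicate"]],
                           meta={"source": str(path)})


def write_titration_csv(dataset: IsothermDataset, path) -> None:
    dataset.data.to_csv(path, index=False)


def write_fit_report(fit: FitResult, path, extra: dict | None = None) -> None:
    """Fit report JSON: estimates, stderr, model id, convergence."""
    report = {"model_id": fit.model_id,
              "estimates": fit.estimates,
              "stderr": fit.stderr,
              "converged": fit.converged,
              "n_replicates": fit.n_replicates}
    if extra:
        report.update(extra)
    write_json(report, path)


_STAB_COLS = ["variant", "subdomain", "environment", "dG_kcal_mol", "err"]


def write_stability_table(results: list[StabilityResult], path) -> None:
    rows = [[r.variant, r.subdomain, r.environment, r.dG, r.err]
            for r in results]
    pd.DataFrame(rows, columns=_STAB_COLS).to_csv(path, sep="\t", index=False)


def read_stability_table(path) -> list[StabilityResult]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_STAB_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [StabilityResult(dG=row.dG_kcal_mol, err=row.err,
                            subdomain=row.subdomain,
                            environment=row.environment, variant=row.variant)
            for row in df.itertuples()]


_DDG_COLS = ["residue", "wt", "mut", "f_ASA", "subdomain", "environment",
             "ddG_N", "ddG_C", "err_N", "err_C"]


def write_ddg_table(records: dict[str, list[DdgRecord]], path) -> None:
    """ΔΔG table TSV, one row per (mutation, environment)."""
    rows = []
    for env, recs in records.items():
        for r in recs:
            m = r.mutation
            rows.append([m.residue_number, m.wt_aa, m.mut_aa, m.f_ASA,
                         m.subdomain_location, env,
                         r.ddG_N, r.ddG_C, r.err_N, r.err_C])
    pd.DataFrame(rows, columns=_DDG_COLS).to_csv(path, sep="\t", index=False)


def read_ddg_table(path) -> dict[str, list[DdgRecord]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_DDG_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[DdgRecord]] = {}
    for row in df.itertuples():
        rec = DdgRecord(
            mutation=MutationRecord(residue_number=int(row.residue),
                                    wt_aa=row.wt, mut_aa=row.mut,
                                    f_ASA=float(row.f_ASA),
                                    subdomain_location=row.subdomain),
            environment=row.environment,
            ddG_N=float(row.ddG_N), ddG_C=float(row.ddG_C),
            err_N=float(row.err_N), err_C=float(row.err_C))
        out.setdefault(row.environment, []).append(rec)
    return out


def write_profile_tsv(profile: CooperativityProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_profile_tsv(path) -> CooperativityProfile:
    df = pd.read_csv(path, sep="\t")
    missing = {"residue", "dddG", "class", "scheme"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    schemes = df["scheme"].unique()
    prof = CooperativityProfile(scheme=schemes[0] if len(schemes) else "regular")
    prof.dddG = dict(zip(df["residue"].astype(int), df["dddG"].astype(float)))
    prof.classes = dict(zip(df["residue"].astype(int), df["class"]))
    return prof


def write_contact_series(series: ContactSeries, path) -> None:
    series.data.to_csv(path, sep="\t", index=False)


def read_contact_series(path, dt: float | None = None) -> ContactSeries:
    df = pd.read_csv(path, sep="\t")
    missing = {"time_ns", "amphiphile_id", "partner", "q"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if dt is None:
        times = np.sort(df["time_ns"].unique())
        if times.size < 2:
            raise ValueError(f"{path}: cannot infer dt from a single time")
        dt = float(np.min(np.diff(times)))
    return ContactSeries(data=df, dt=dt)


def write_autocorr_tsv(curve: AutocorrCurve, path) -> None:
    pd.DataFrame({"tau_ns": curve.tau_ns, "c": curve.c}).to_csv(
        path, sep="\t", index=False)


def read_autocorr_tsv(path, n_events: int = 0) -> AutocorrCurve:
    df = pd.read_csv(path, sep="\t")
    missing = {"tau_ns", "c"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return AutocorrCurve(tau_ns=df["tau_ns"].to_numpy(float),
                         c=df["c"].to_numpy(float), n_events=n_events)


# ---------------------------------------------------------------------------
# coordinate frames: multi-model PDB + chain-type sidecar

_TYPE_TO_CHAIN = {"protein": "A", "lipid": "L", "detergent": "D", "other": "X"}


def write_frames_pdb(frames: FrameSet, path, typemap_path=None) -> None:
    """Write frames as a multi-model PDB plus a chain→type sidecar TSV.

    Protein atoms keep their residue ids on one chain; each amphiphile
    molecule becomes one residue on its type's chain. The sidecar maps
    chain ids to molecule types for :func:`read_frames_pdb`.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = len(frames.atoms)
    arr = struc.AtomArrayStack(frames.n_frames, n_atoms)
    arr.coord = frames.coords.copy()
    chain_ids = np.empty(n_atoms, dtype="U4")
    res_ids = np.zeros(n_atoms, dtype=int)
    res_names = np.empty(n_atoms, dtype="U5")
    # distinct residue number per amphiphile molecule, per chain
    mol_res: dict[object, int] = {}
    counters = {c: 0 for c in _TYPE_TO_CHAIN.values()}
    for i, row in enumerate(frames.atoms.itertuples()):
        mtype = row.molecule_type
        chain = _TYPE_TO_CHAIN[mtype]
        chain_ids[i] = chain
        if mtype == "protein":
            res_ids[i] = int(row.residue_id)
            res_names[i] = "GLY"
        else:
            key = (chain, row.molecule_id)
            if key not in mol_res:
                counters[chain] += 1
                mol_res[key] = counters[chain]
            res_ids[i] = mol_res[key]
            res_names[i] = {"lipid": "DMP", "detergent": "DDM",
                            "other": "UNK"}[mtype]
    arr.chain_id = chain_ids
    arr.res_id = res_ids
    arr.res_name = res_names
    arr.atom_name = frames.atoms["atom_name"].to_numpy(dtype="U6")
    arr.element = np.array(
        [("H" if n.upper().startswith("H") else n[0].upper())
         for n in frames.atoms["atom_name"]], dtype="U2")
    arr.hetero = np.array([t != "protein"
                           for t in frames.atoms["molecule_type"]])
    pdbfile = pdb.PDBFile()
    pdbfile.set_structure(arr)
    pdbfile.write(str(path))
    if typemap_path is not None:
        used = sorted(set(chain_ids.tolist()))
        rev = {v: k for k, v in _TYPE_TO_CHAIN.items()}
        pd.DataFrame({"chain_id": used,
                      "molecule_type": [rev[c] for c in used]}).to_csv(
            typemap_path, sep="\t", index=False)


def read_frames_pdb(path, typemap_path, dt: float = 1.0) -> FrameSet:
    """Read a multi-model PDB into a FrameSet.

    The sidecar TSV (columns ``chain_id``, ``molecule_type``) assigns a
    type to every chain; protein chains form one molecule each, while
    every residue of a non-protein chain is its own molecule
    (id ``chain:res_id``). Chains absent from the map raise an error
    naming the chain; model rosters must agree.
    """
    import biotite.structure.io.pdb as pdb

    tmap = pd.read_csv(typemap_path, sep="\t")
    missing = {"chain_id", "molecule_type"} - set(tmap.columns)
    if missing:
        raise ValueError(f"{typemap_path}: missing columns {sorted(missing)}")
    chain_type = dict(zip(tmap["chain_id"].astype(str),
                          tmap["molecule_type"]))

    pdbfile = pdb.PDBFile.read(str(path))
    try:
        stack = pdbfile.get_structure()   # raises if rosters mismatch
    except Exception as exc:
        raise ValueError(f"{path}: inconsistent MODEL records ({exc})") from exc
    coords = np.asarray(stack.coord)
    chains = stack.chain_id
    unknown = sorted(set(chains.tolist()) - set(chain_type))
    if unknown:
        raise ValueError(f"{path}: chains {unknown} missing from typemap "
                         f"{typemap_path}")
    mol_ids, mol_types = [], []
    for chain, res in zip(chains, stack.res_id):
        mtype = chain_type[str(chain)]
        mol_types.append(mtype)
        mol_ids.append(str(chain) if mtype == "protein" else f"{chain}:{res}")
    atoms = pd.DataFrame({"atom_name": stack.atom_name,
                          "residue_id": stack.res_id,
                          "molecule_id": mol_ids,
                          "molecule_type": mol_types,
                          "element": stack.element})
    return FrameSet(atoms=atoms, coords=coords, dt=dt)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")
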