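"""Readers and writers for trajectories, topology/parameter tables and run configs.

Multi-frame XYZ (coordinates in nm, comment line carrying the step index
and optional box) is the canonical trajectory dialect; PDB is accepted for
structures and trajectories through mdtraj (which converts Angstrom to
nm).  Topology and parameter tables are tab-separated text with explicit
section headers; energies given in kcal/mol are converted on read and the
conversion logged.  All bead indices in files are 0-based.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .cgmodel import CGTopology, NonbondedParams, PairEntry, pair_key
from .ensemble import Ensemble
from .remtrain import RegConfig, TrainResult
from .simulate import SimSettings
from .units import KCAL

log = logging.getLogger("regcg")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def read_trajectory(path, fmt: str | None = None) -> Ensemble:
    """Read a multi-frame XYZ (nm) or PDB (Angstrom, converted) trajectory."""
    path = Path(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() == ".pdb" else "xyz"
    if fmt == "pdb":
        import mdtraj

        traj = mdtraj.load(str(path))
        return Ensemble(coords=np.asarray(traj.xyz, dtype=np.float64))
    if fmt != "xyz":
        raise ValueError(f"unknown trajectory format {fmt!r}")

    frames = []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_expected = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(
                f"{path}: expected atom count at line {i + 1}, got {lines[i]!r}"
            ) from None
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise ValueError(
                f"{path}: frame {len(frames)} has {n} particles, expected {n_expected}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        if "box=" in comment:
            box = np.array([float(x) for x in
                            comment.split("box=")[1].split()[0].split(",")])
        rows = lines[i + 2 : i + 2 + n]
        if len(rows) < n:
            raise ValueError(f"{path}: truncated frame {len(frames)}")
        coords = np.empty((n, 3))
        for k, row in enumerate(rows):
            parts = row.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: malformed coordinate line in frame {len(frames)}: {row!r}"
                )
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Ensemble(coords=np.array(frames), box=box)


def write_trajectory(path, ensemble: Ensemble, labels=None, precision: int = 6) -> None:
    """Write a multi-frame XYZ file in nm."""
    path = Path(path)
    if labels is None:
        labels = [f"B{i}" for i in range(ensemble.n_beads)]
    box = ""
    if ensemble.box is not None:
        box = " box=" + ",".join(f"{x:.{precision}f}" for x in ensemble.box)
    with open(path, "w") as fh:
        for k in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_beads}\n")
            fh.write(f"frame={k}{box}\n")
            for lab, (x, y, z) in zip(labels, ensemble.coords[k]):
                fh.write(f"{lab} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}\n")


# ---------------------------------------------------------------------------
# topology tables
# ---------------------------------------------------------------------------

def write_topology(path, topology: CGTopology) -> None:
    with open(path, "w") as fh:
        fh.write("[beads]\n")
        fh.write("bead_id\tmonomer_id\ttype\tcharge_e\tmass_u\n")
        for i in range(topology.n_beads):
            fh.write(
                f"{i}\t{topology.monomer_id[i]}\t{topology.bead_type[i]}"
                f"\t{topology.charge[i]:.6g}\t{topology.mass[i]:.6g}\n"
            )
        fh.write("[springs]\n")
        fh.write("bead_i\tbead_j\tk_kj_mol_nm2\tr0_nm\n")
        for s in range(topology.spring_i.size):
            fh.write(
                f"{topology.spring_i[s]}\t{topology.spring_j[s]}"
                f"\t{topology.spring_k[s]:.8g}\t{topology.spring_r0[s]:.8g}\n"
            )


def read_topology(path) -> CGTopology:
    sections = _read_sections(path, {"beads", "springs"})
    beads = sections["beads"]
    _check_header(beads[0], ["bead_id", "monomer_id", "type", "charge_e", "mass_u"], path)
    rows = [r.split("\t") for r in beads[1:]]
    ids = [int(r[0]) for r in rows]
    if ids != list(range(len(ids))):
        raise ValueError(f"{path}: bead_ids must be contiguous from 0")
    topo = CGTopology(
        monomer_id=np.array([int(r[1]) for r in rows]),
        bead_type=[r[2] for r in rows],
        charge=np.array([float(r[3]) for r in rows]),
        mass=np.array([float(r[4]) for r in rows]),
    )
    springs = sections.get("springs", [])
    if len(springs) > 1:
        _check_header(springs[0], ["bead_i", "bead_j", "k_kj_mol_nm2", "r0_nm"], path)
        srows = [r.split("\t") for r in springs[1:]]
        topo = topo.with_springs(
            [int(r[0]) for r in srows],
            [int(r[1]) for r in srows],
            [float(r[2]) for r in srows],
            [float(r[3]) for r in srows],
        )
    return topo


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

_GLOBAL_KEYS = {"sigma": "nm", "B": "kj_mol_nm4", "eps_r": "1",
                "kappa_D": "nm-1", "cutoff": "nm"}


def write_params(path, params: NonbondedParams) -> None:
    with open(path, "w") as fh:
        fh.write("[globals]\n")
        fh.write("name\tvalue\tunit\n")
        for key, unit in _GLOBAL_KEYS.items():
            fh.write(f"{key}\t{getattr(params, key):.10g}\t{unit}\n")
        fh.write("[pairs]\n")
        fh.write("type_i\ttype_j\tA_kj_mol\tR_rep_nm\tC_kj_mol_nm\tR_att_nm"
                 "\ttrainable\tb_enabled\n")
        for (ti, tj), e in sorted(params.pairs.items()):
            fh.write(
                f"{ti}\t{tj}\t{e.A:.10g}\t{e.R_rep:.10g}\t{e.C:.10g}"
                f"\t{e.R_att:.10g}\t{int(e.trainable)}\t{int(e.b_enabled)}\n"
            )


def read_params(path) -> NonbondedParams:
    sections = _read_sections(path, {"globals", "pairs"})
    glob_rows = [r.split("\t") for r in sections["globals"][1:]]
    globs: dict[str, float] = {}
    for name, value, unit in glob_rows:
        if name not in _GLOBAL_KEYS:
            raise ValueError(f"{path}: unknown global parameter {name!r}")
        v = float(value)
        if unit.startswith("kcal"):
            v *= KCAL
            log.info("converted %s from kcal to kJ: %g", name, v)
        globs[name] = v
    missing = set(_GLOBAL_KEYS) - set(globs)
    if missing:
        raise ValueError(f"{path}: missing globals {sorted(missing)}")

    pair_rows = sections["pairs"]
    _check_header(
        pair_rows[0],
        ["type_i", "type_j", "A_kj_mol", "R_rep_nm", "C_kj_mol_nm", "R_att_nm",
         "trainable", "b_enabled"],
        path,
    )
    pairs: dict[tuple[str, str], PairEntry] = {}
    for row in pair_rows[1:]:
        ti, tj, a, rrep, c, ratt, tr, ben = row.split("\t")
        pairs[pair_key(ti, tj)] = PairEntry(
            A=float(a), R_rep=float(rrep), C=float(c), R_att=float(ratt),
            trainable=bool(int(tr)), b_enabled=bool(int(ben)),
        )
    return NonbondedParams(pairs=pairs, **globs)


def _read_sections(path, known: set[str]) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                name = line[1:-1]
                if name not in known:
                    raise ValueError(f"{path}: unknown section [{name}]")
                current = sections.setdefault(name, [])
                continue
            if current is None:
                raise ValueError(f"{path}: data before any section header")
            current.append(line)
    if not sections:
        raise ValueError(f"{path}: empty file")
    return sections


def _check_header(line: str, expected: list[str], path) -> None:
    got = line.split("\t")
    if got != expected:
        raise ValueError(f"{path}: bad header {got}; expected {expected}")


# ---------------------------------------------------------------------------
# mapping files
# ---------------------------------------------------------------------------

def write_mapping(path, spec) -> None:
    with open(path, "w") as fh:
        fh.write("fine_index\tbead_id\n")
        for i, b in enumerate(spec.bead_of):
            fh.write(f"{i}\t{b}\n")


def read_mapping(path, weight_scheme: str = "mass"):
    from .mapping import MappingSpec

    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    _check_header(lines[0], ["fine_index", "bead_id"], path)
    rows = [ln.split("\t") for ln in lines[1:]]
    idx = [int(r[0]) for r in rows]
    if idx != list(range(len(idx))):
        raise ValueError(f"{path}: fine indices must be contiguous from 0")
    return MappingSpec(np.array([int(r[1]) for r in rows]), weight_scheme)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_SIM_KEYS = {"dt", "temperature", "friction", "n_steps", "stride", "seed",
             "wall_radius"}
_TRAIN_KEYS = {"V0", "kappa_reg", "gamma", "n_iterations", "vbind_pair",
               "max_step", "seed", "early_stop_tol", "early_stop_window",
               "unbound_threshold"}


def read_config(path) -> tuple[SimSettings, RegConfig]:
    """Parse a YAML run configuration with ``simulation:`` and ``training:`` blocks.

    Unknown keys are rejected by name; ``kappa_reg_kcal`` may be used to give
    the regularization strength in (kcal/mol)^-2, converted on read.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"simulation", "training"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    sim_raw = dict(raw.get("simulation", {}))
    bad = set(sim_raw) - _SIM_KEYS
    if bad:
        raise ValueError(f"{path}: unknown simulation keys {sorted(bad)}")
    sim = SimSettings(**sim_raw)

    train_raw = dict(raw.get("training", {}))
    if "kappa_reg_kcal" in train_raw:
        train_raw["kappa_reg"] = train_raw.pop("kappa_reg_kcal") / KCAL**2
        log.info("converted kappa_reg from (kcal/mol)^-2: %g", train_raw["kappa_reg"])
    bad = set(train_raw) - _TRAIN_KEYS
    if bad:
        raise ValueError(f"{path}: unknown training keys {sorted(bad)}")
    if "vbind_pair" in train_raw and train_raw["vbind_pair"] is not None:
        train_raw["vbind_pair"] = tuple(train_raw["vbind_pair"])
    cfg = RegConfig(sim=sim, **train_raw)
    return sim, cfg


# ---------------------------------------------------------------------------
# training logs and manifests
# ---------------------------------------------------------------------------

def write_train_log(path, result: TrainResult) -> None:
    """Tab-separated per-iteration log (directly plottable)."""
    with open(path, "w") as fh:
        fh.write("iteration\tv_bind_mean\trmsd_mean\tgrad_kl_norm"
                 "\tgrad_reg_norm\tunbound_fraction\n")
        for r in result.records:
            fh.write(
                f"{r.iteration}\t{r.v_bind_mean:.6g}\t{r.rmsd_mean:.6g}"
                f"\t{np.linalg.norm(r.grad_kl):.6g}"
                f"\t{np.linalg.norm(r.grad_reg):.6g}"
                f"\t{r.unbound_fraction:.4g}\n"
            )


def write_manifest(path, seed: int, config_files: list, extra: dict | None = None) -> None:
    """Record seed, package version and input hashes for reproducibility."""
    from . import __version__

    entry = {
        "seed": seed,
        "regcg_version": __version__,
        "inputs": {},
    }
    for f in config_files:
        f = Path(f)
        if f.exists():
            entry["inputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
    if extra:
        entry.update(extra)
    with open(path, "w") as fh:
        json.dump(entry, fh, indent=2)
        fh.write("\n")
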