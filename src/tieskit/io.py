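"""File formats and run layout.

Gradient data live in a TSV dialect under the directory convention
``<transformation>/<leg>/lambda_<value>/rep_<k>.tsv`` — one file per
replica per window, with '#'-prefixed header metadata (transformation,
leg, lambda, replica, interval_ps, units) followed by two tab-separated
columns ``time_ps`` and ``dudl``. kcal/mol is the canonical unit;
kJ/mol inputs are converted on read (factor 4.184) and logged.

A best-effort importer for NAMD-style alchemical output extracts per-step
∂U/∂λ records through a configurable regular-expression profile; engine
output grammars vary by version, so the profile is a dialect description,
not a fidelity claim.

Ligand structures are read from TRIPOS MOL2 (charges from the charge
column; parsed directly, since force-field-typed MOL2 files produced by
antechamber fall outside rdkit's Sybyl-type support) and from SDF with a
named partial-charge property (one value per atom line) via rdkit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, IOFormatError
from .free_energy import COMPLEX, LIGAND, DDGResult, GradientSamples, WindowEnsemble
from .lambda_protocol import ProtocolConfig
from .ligand_topology import AtomRecord, HybridTopology, LigandGraph

log = logging.getLogger("tieskit")

KJ_PER_KCAL = 4.184
RESULTS_SCHEMA_VERSION = 1

LEGS = (COMPLEX, LIGAND)


def format_lambda(lam: float) -> str:
    """Trailing-zero-free decimal rendering used in directory names."""
    s = f"{lam:.9f}".rstrip("0").rstrip(".")
    return s if s else "0"


# ---------------------------------------------------------------------------
# Gradient TSV dialect
# ---------------------------------------------------------------------------

def write_gradient_tsv(path, gs: GradientSamples) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"# transformation: {gs.transformation_id}",
        f"# leg: {gs.leg}",
        f"# lambda: {format_lambda(gs.lam)}",
        f"# replica: {gs.replica}",
        f"# interval_ps: {gs.interval_ps:g}",
        "# units: kcal/mol",
        "time_ps\tdudl",
    ]
    for i, v in enumerate(gs.samples):
        lines.append(f"{i * gs.interval_ps:g}\t{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_gradient_tsv(path) -> GradientSamples:
    path = Path(path)
    meta: dict[str, str] = {}
    values = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            cols = line.split("\t")
            if cols != ["time_ps", "dudl"]:
                raise IOFormatError(f"expected column header 'time_ps\\tdudl', got {line!r}",
                                    path=path, line=lineno)
            header_seen = True
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise IOFormatError(f"expected 2 columns, got {len(cols)}",
                                path=path, line=lineno)
        try:
            values.append(float(cols[1]))
        except ValueError:
            raise IOFormatError(f"non-numeric dudl value {cols[1]!r}",
                                path=path, line=lineno) from None

    units = meta.get("units", "kcal/mol").lower()
    samples = np.asarray(values, dtype=float)
    if units in ("kj/mol", "kj·mol-1", "kjmol"):
        samples = samples / KJ_PER_KCAL
        log.info("converted %s from kJ/mol to kcal/mol", path)
    elif units != "kcal/mol":
        raise IOFormatError(f"unsupported units {meta.get('units')!r}", path=path)
    try:
        return GradientSamples(
            transformation_id=meta.get("transformation", ""),
            leg=meta.get("leg", ""),
            lam=float(meta["lambda"]),
            replica=int(meta.get("replica", 1)),
            samples=samples,
            interval_ps=float(meta.get("interval_ps", 2.0)),
        )
    except KeyError as e:
        raise IOFormatError(f"missing header key {e}", path=path) from None


# ---------------------------------------------------------------------------
# Run layout
# ---------------------------------------------------------------------------

def write_gradients(root, complex_ens: WindowEnsemble,
                    ligand_ens: WindowEnsemble) -> Path:
    """Write both legs of one transformation under the run layout."""
    root = Path(root)
    for ens in (complex_ens, ligand_ens):
        base = root / ens.transformation_id / ens.leg
        for lam, reps in ens.windows.items():
            for gs in reps:
                write_gradient_tsv(
                    base / f"lambda_{format_lambda(lam)}" / f"rep_{gs.replica}.tsv", gs)
    return root / complex_ens.transformation_id


def read_gradients(root, protocol: ProtocolConfig | None = None,
                   transformation: str | None = None
                   ) -> tuple[WindowEnsemble, WindowEnsemble]:
    """Read one transformation's two legs from the run layout.

    The λ directories found must match the protocol schedule exactly
    (numeric tolerance 1e-9); the error message lists any missing or
    extra windows. Replica files must be numbered from 1 without gaps.
    """
    protocol = protocol or ProtocolConfig()
    root = Path(root)
    if transformation is None:
        candidates = sorted(p.name for p in root.iterdir() if p.is_dir())
        if len(candidates) != 1:
            raise IOFormatError(
                f"expected a single transformation directory, found {candidates}",
                path=root)
        transformation = candidates[0]
    tdir = root / transformation

    ensembles = []
    for leg in LEGS:
        ldir = tdir / leg
        if not ldir.is_dir():
            raise IOFormatError(f"missing leg directory {leg!r}", path=tdir)
        found = {}
        for wdir in sorted(ldir.glob("lambda_*")):
            try:
                found[float(wdir.name.removeprefix("lambda_"))] = wdir
            except ValueError:
                raise IOFormatError(f"malformed window directory {wdir.name!r}",
                                    path=ldir) from None
        sched = list(protocol.window_values)
        missing = [lam for lam in sched
                   if not any(abs(lam - f) <= 1e-9 for f in found)]
        extra = [f for f in found
                 if not any(abs(lam - f) <= 1e-9 for lam in sched)]
        if missing or extra:
            raise IOFormatError(
                "window layout does not match protocol schedule; missing: "
                f"{[format_lambda(x) for x in missing]}, extra: "
                f"{[format_lambda(x) for x in extra]}", path=ldir)
        windows = {}
        for f, wdir in found.items():
            lam = next(lam for lam in sched if abs(lam - f) <= 1e-9)
            reps = [read_gradient_tsv(p) for p in sorted(
                wdir.glob("rep_*.tsv"),
                key=lambda p: int(p.stem.removeprefix("rep_")))]
            if not reps:
                raise IOFormatError("no replica files", path=wdir)
            indices = [r.replica for r in reps]
            if indices != list(range(1, len(reps) + 1)):
                raise IOFormatError(
                    f"replica numbering not gapless from 1: {indices}", path=wdir)
            for r in reps:
                r.lam = lam  # normalize to the schedule's exact value
            windows[lam] = reps
        ensembles.append(WindowEnsemble(transformation, leg, windows))
    return ensembles[0], ensembles[1]


# ---------------------------------------------------------------------------
# NAMD-style alchemical output (best effort)
# ---------------------------------------------------------------------------

#: Default dialect profile: lines like "TI: <step> <dU/dλ> ..." with the
#: gradient in the named group. Override per engine version.
NAMD_TI_PROFILE = re.compile(
    r"^TI:\s+(?P<step>\d+)\s+(?P<dudl>[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)")


def parse_namd_alch(path, transformation_id: str = "", leg: str = "",
                    lam: float = 0.0, replica: int = 1,
                    interval_ps: float = 2.0,
                    profile: re.Pattern = NAMD_TI_PROFILE) -> GradientSamples:
    """Extract per-step ∂U/∂λ records from engine output, best effort.

    Only lines matching the dialect profile are consumed; interleaved
    unrelated output is ignored. Raises when no record matches.
    """
    path = Path(path)
    values = [float(m.group("dudl"))
              for line in path.read_text().splitlines()
              if (m := profile.match(line))]
    if not values:
        raise IOFormatError("no alchemical records matched the dialect profile",
                            path=path)
    return GradientSamples(transformation_id=transformation_id, leg=leg,
                           lam=lam, replica=replica,
                           samples=np.asarray(values), interval_ps=interval_ps)


# ---------------------------------------------------------------------------
# Ligand structures
# ---------------------------------------------------------------------------

_MOL2_ELEMENT = re.compile(r"^([A-Z][a-z]?)")


def read_mol2(path) -> LigandGraph:
    """Read a TRIPOS MOL2 ligand; partial charges from the charge column.

    The element is the leading capitalised part of the SYBYL atom type
    (``C.ar`` → C); for lowercase force-field types (GAFF ``ca``, ``ha``)
    it falls back to the capitalized leading letters of the atom name.
    """
    path = Path(path)
    section = None
    atoms, bonds = [], []
    id_map: dict[int, int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line.removeprefix("@<TRIPOS>").strip().upper()
            continue
        if not line or line.startswith("#"):
            continue
        if section == "ATOM":
            cols = line.split()
            if len(cols) < 6:
                raise IOFormatError("ATOM record needs >= 6 columns", path=path,
                                    line=lineno)
            try:
                orig_id = int(cols[0])
                x, y, z = (float(c) for c in cols[2:5])
                charge = float(cols[8]) if len(cols) > 8 else 0.0
            except ValueError:
                raise IOFormatError(f"malformed ATOM record {line!r}", path=path,
                                    line=lineno) from None
            elem = _element_from_mol2(cols[5], cols[1])
            id_map[orig_id] = len(atoms)
            atoms.append(AtomRecord(len(atoms), elem, cols[1], charge, (x, y, z)))
        elif section == "BOND":
            cols = line.split()
            if len(cols) < 4:
                raise IOFormatError("BOND record needs >= 4 columns", path=path,
                                    line=lineno)
            try:
                i, j = id_map[int(cols[1])], id_map[int(cols[2])]
            except (ValueError, KeyError):
                raise IOFormatError(f"malformed BOND record {line!r}", path=path,
                                    line=lineno) from None
            order = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 1, "du": 1}.get(
                cols[3].lower(), 1)
            bonds.append((i, j, order))
    if not atoms:
        raise IOFormatError("no ATOM section found", path=path)
    return LigandGraph(atoms, bonds, name=path.stem)


def _element_from_mol2(atom_type: str, atom_name: str) -> str:
    base = atom_type.split(".")[0]
    m = _MOL2_ELEMENT.match(base)
    if m:
        return m.group(1)
    # lowercase force-field type: infer from the atom name (N1, Cl2, ...)
    m = re.match(r"^([A-Za-z]{1,2})", atom_name)
    if not m:
        raise IOFormatError(f"cannot infer element from type {atom_type!r} "
                            f"/ name {atom_name!r}")
    sym = m.group(1)
    return sym.capitalize() if len(sym) == 2 and sym[1].islower() else sym[0].upper()


def read_sdf(path, charge_property: str = "PartialCharges") -> LigandGraph:
    """Read the first molecule of an SDF; charges from a named property.

    The property holds one charge value per atom line (whitespace or
    newline separated), in atom order.
    """
    from rdkit import Chem

    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise IOFormatError("no readable molecule in SDF", path=path)
    if not mol.HasProp(charge_property):
        raise IOFormatError(f"SDF molecule lacks charge property {charge_property!r}",
                            path=path)
    charges = [float(tok) for tok in mol.GetProp(charge_property).split()]
    if len(charges) != mol.GetNumAtoms():
        raise IOFormatError(
            f"charge property has {len(charges)} values for {mol.GetNumAtoms()} atoms",
            path=path)
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        coords = None
        if conf is not None:
            p = conf.GetAtomPosition(i)
            coords = (p.x, p.y, p.z)
        atoms.append(AtomRecord(i, atom.GetSymbol(), f"{atom.GetSymbol()}{i + 1}",
                                charges[i], coords))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
              max(1, int(b.GetBondTypeAsDouble())))
             for b in mol.GetBonds()]
    return LigandGraph(atoms, bonds, name=path.stem)


def read_ligand(path, charge_property: str = "PartialCharges") -> LigandGraph:
    """Dispatch on extension: .mol2 or .sdf/.sd."""
    suffix = Path(path).suffix.lower()
    if suffix == ".mol2":
        return read_mol2(path)
    if suffix in (".sdf", ".sd"):
        return read_sdf(path, charge_property)
    raise ConfigurationError(f"unsupported ligand format {suffix!r}")


# ---------------------------------------------------------------------------
# Results and provenance
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(seed=None, config=None) -> dict:
    from . import __version__
    return {"tool": "tieskit", "version": __version__,
            "config_hash": config_hash(config or {}), "master_seed": seed}


def ddg_result_to_doc(res: DDGResult, seed=None, config=None) -> dict:
    def leg_doc(leg):
        if leg is None:
            return None
        return {
            "leg": leg.leg, "delta_g": leg.delta_g, "sigma": leg.sigma,
            "ensemble_size": leg.ensemble_size, "n_boot": leg.n_boot,
            "per_window": [{"lambda": l, "mean": m, "se": s}
                           for l, m, s in leg.per_window],
        }

    return {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "transformation_id": res.transformation_id,
        "ddg": res.ddg,
        "sigma": res.sigma,
        "ensemble_size": res.ensemble_size,
        "legs": {COMPLEX: leg_doc(res.complex_leg), LIGAND: leg_doc(res.ligand_leg)},
        "provenance": provenance(seed, config),
    }


def write_json(path, doc) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def hybrid_to_pdb(h: HybridTopology, a: LigandGraph, b: LigandGraph) -> str:
    """Merged-coordinate PDB of a hybrid (requires coords on both ligands)."""
    amap = h.mcs.as_dict()
    records = []
    serial = 0
    for region, src, ids in (("mcs", a, sorted(amap)),
                             ("dis", a, sorted(h.disappearing)),
                             ("app", b, sorted(h.appearing))):
        for i in ids:
            atom = src.atom(i)
            if atom.coords is None:
                raise ConfigurationError("PDB output requires coordinates on all atoms")
            serial += 1
            x, y, z = atom.coords
            name = (atom.name or atom.element)[:4]
            records.append(
                f"HETATM{serial:>5} {name:<4} {'HYB':<3} A{1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element:>2}")
    records.append("END")
    return "\n".join(records) + "\n"
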