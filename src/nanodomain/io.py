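"""Readers and writers for the formats the pipeline touches.

* localization tables: CSV with a header row (default columns ``x_nm``,
  ``y_nm``, ``frame``, ``channel``, ``precision_nm``; other dialects via
  a column map, including unit conversion to nm);
* polarization image pairs: single-channel TIFFs (or one two-page
  TIFF), counts preserved exactly; float maps written as 32-bit TIFF;
* bilayer coordinate frames: PDB or GRO through MDAnalysis, mapped onto
  :class:`~nanodomain.bilayer.BilayerEnsemble` via a species-definition
  schema (YAML/JSON) that names anchor, headgroup, and chain atoms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .anisotropy import PolarizedImagePair
from .bilayer import BilayerEnsemble, Lipid
from .errors import SchemaError, StructuralError
from .spatial import LocalizationTable

log = logging.getLogger(__name__)

_UNIT_TO_NM = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "micron": 1000.0, "px": None}


@dataclass
class ColumnMap:
    """Mapping from CSV dialect column names to the canonical schema."""

    x: str = "x_nm"
    y: str = "y_nm"
    frame: str | None = "frame"
    channel: str | None = "channel"
    precision: str | None = "precision_nm"
    xy_unit: str = "nm"

    @classmethod
    def thunderstorm(cls) -> "ColumnMap":
        return cls(x="x [nm]", y="y [nm]", frame="frame",
                   channel=None, precision="uncertainty [nm]")


def read_localization_csv(path, column_map: ColumnMap | dict | None = None) -> LocalizationTable:
    """Read a localization table, normalizing coordinates to nm.

    Malformed rows (non-numeric coordinates) are rejected with their
    line numbers logged; missing mandatory columns raise a schema error
    listing the headers actually present.
    """
    cmap = _as_colmap(column_map)
    df = pd.read_csv(path)
    for needed in (cmap.x, cmap.y):
        if needed not in df.columns:
            raise SchemaError(
                f"column {needed!r} missing from {path}; available: {list(df.columns)}"
            )
    scale = _UNIT_TO_NM.get(cmap.xy_unit)
    if scale is None:
        raise SchemaError(f"unsupported coordinate unit {cmap.xy_unit!r}")
    out = pd.DataFrame({
        "x": pd.to_numeric(df[cmap.x], errors="coerce") * scale,
        "y": pd.to_numeric(df[cmap.y], errors="coerce") * scale,
    })
    for attr, col in (("frame", cmap.frame), ("channel", cmap.channel),
                      ("precision", cmap.precision)):
        if col is not None and col in df.columns:
            vals = df[col]
            if attr == "precision":
                vals = pd.to_numeric(vals, errors="coerce") * scale
            out[attr] = vals
    bad = out["x"].isna() | out["y"].isna()
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # +2: header + 1-based
        log.warning("%s: rejected %d malformed rows at lines %s", path, bad.sum(), lines)
        out = out[~bad]
    return LocalizationTable(out)


def _as_colmap(column_map) -> ColumnMap:
    if column_map is None:
        return ColumnMap()
    if isinstance(column_map, ColumnMap):
        return column_map
    return ColumnMap(**column_map)


def write_localization_csv(table: LocalizationTable, path) -> None:
    """Write in the default dialect (x_nm, y_nm, frame, channel, precision_nm)."""
    rename = {"x": "x_nm", "y": "y_nm", "precision": "precision_nm"}
    table.data.rename(columns=rename).to_csv(path, index=False)


def read_image_pair(
    parallel_path,
    perpendicular_path=None,
    pixel_size: float | None = None,
    background_parallel: float = 0.0,
    background_perpendicular: float = 0.0,
) -> PolarizedImagePair:
    """Read a polarization pair from two TIFFs or one two-page TIFF.

    Integer counts are preserved exactly.  ``pixel_size`` (nm) comes
    from the caller's configuration; TIFF resolution tags are used as a
    fallback when present.
    """
    if perpendicular_path is None:
        with tifffile.TiffFile(parallel_path) as tf:
            if len(tf.pages) < 2:
                raise StructuralError(
                    f"{parallel_path} has {len(tf.pages)} page(s); need 2 or a second file"
                )
            par = tf.pages[0].asarray()
            perp = tf.pages[1].asarray()
    else:
        par = tifffile.imread(parallel_path)
        perp = tifffile.imread(perpendicular_path)
    if par.shape != perp.shape:
        raise StructuralError(f"channel shapes differ: {par.shape} vs {perp.shape}")
    if par.dtype.kind not in "uif":
        raise StructuralError(f"unsupported TIFF dtype {par.dtype}")
    if pixel_size is None:
        pixel_size = _pixel_size_from_tags(parallel_path) or 1.0
    return PolarizedImagePair(par, perp, pixel_size,
                              background_parallel, background_perpendicular)


def _pixel_size_from_tags(path) -> float | None:
    try:
        with tifffile.TiffFile(path) as tf:
            tags = tf.pages[0].tags
            if "XResolution" in tags:
                num, den = tags["XResolution"].value
                if num:
                    return float(den) / float(num)  # pixels-per-unit -> unit-per-pixel
    except Exception:  # noqa: BLE001 - fallback only
        pass
    return None


def write_image_pair(pair: PolarizedImagePair, parallel_path, perpendicular_path) -> None:
    tifffile.imwrite(parallel_path, np.asarray(pair.parallel))
    tifffile.imwrite(perpendicular_path, np.asarray(pair.perpendicular))


def write_float_map(array: np.ndarray, path) -> None:
    """Write an analysis map (anisotropy, total intensity) as float32 TIFF."""
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


# --------------------------------------------------------------------------
# bilayer coordinates
# --------------------------------------------------------------------------

def load_species_schema(path) -> dict:
    """Load a species-definition schema from YAML or JSON."""
    text = Path(path).read_text()
    schema = yaml.safe_load(text)
    if not isinstance(schema, dict) or "species" not in schema:
        raise SchemaError(f"{path}: schema must be a mapping with a 'species' block")
    return schema


def read_bilayer_frames(paths, schema: dict, recenter: bool = False) -> BilayerEnsemble:
    """Read PDB/GRO coordinate frames into a BilayerEnsemble.

    ``paths`` is one file, a list of files (one per frame), or a
    (topology, trajectory) pair readable by MDAnalysis.  The schema maps
    residue names to species and declares anchor / headgroup / chain
    atom names; unresolved names raise a schema error naming the lipid
    and atom.  Coordinates are converted to nm.  With ``recenter`` the
    per-frame z-COM of terminal chain carbons is shifted to zero.
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, Path)):
        u = mda.Universe(str(paths))
    else:
        paths = [str(p) for p in paths]
        u = mda.Universe(paths[0], paths) if len(paths) > 1 else mda.Universe(paths[0])

    by_resname = {}
    for sp_name, sp in schema["species"].items():
        for rn in sp.get("resnames", [sp_name]):
            by_resname[rn] = (sp_name, sp)

    lipids = []
    for res in u.residues:
        if res.resname not in by_resname:
            continue
        sp_name, sp = by_resname[res.resname]
        names = {a.name: a.ix for a in res.atoms}

        def resolve(atom_name, res=res):
            if atom_name not in names:
                raise SchemaError(
                    f"lipid {res.resid} ({res.resname}): atom {atom_name!r} not found"
                )
            return int(names[atom_name])

        atoms = {}
        anchor = resolve(sp["anchor"]) if "anchor" in sp else None
        if anchor is not None:
            atoms[sp["anchor"]] = anchor
        for hname in sp.get("headgroup", []):
            atoms[hname] = resolve(hname)
        chains = {cname: [resolve(a) for a in atom_list]
                  for cname, atom_list in sp.get("chains", {}).items()}
        leaflet = sp.get("leaflet", "auto")
        if leaflet == "auto":
            ref = anchor if anchor is not None else res.atoms[0].ix
            leaflet = "upper" if u.atoms.positions[ref][2] >= np.mean(
                u.atoms.positions[:, 2]) else "lower"
        lipids.append(Lipid(int(res.resid), sp_name, leaflet, anchor, atoms, chains))
    if not lipids:
        raise SchemaError("no residues matched the schema's species")

    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(u.atoms), 3))
    boxes = np.empty((n_frames, 3))
    for f, ts in enumerate(u.trajectory):
        coords[f] = ts.positions / 10.0  # A -> nm
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise StructuralError(f"frame {f} lacks box dimensions")
        boxes[f] = ts.dimensions[:3] / 10.0
    expected = schema.get("box")
    if expected is not None and not np.allclose(boxes[0], expected, rtol=1e-3):
        raise SchemaError(
            f"box {boxes[0].tolist()} does not match schema expectation {expected}"
        )
    box = boxes[0] if np.allclose(boxes, boxes[0]) else boxes
    ens = BilayerEnsemble(coords, box, lipids)
    if recenter:
        idx = [c[-1] for lip in lipids for c in lip.chains.values() if c]
        if idx:
            ens.coords[:, :, 2] -= ens.coords[:, idx, 2].mean(axis=1, keepdims=True)
    return ens


def write_bilayer_frames(ensemble: BilayerEnsemble, out_dir, fmt: str = "gro",
                         prefix: str = "frame") -> list:
    """Write each frame as a PDB or GRO file; returns the paths.

    Lipids become residues; atom names are taken from the named-atom
    and chain annotations (generic C<k> names fill any gap).
    """
    import MDAnalysis as mda

    fmt = fmt.lower()
    if fmt not in ("gro", "pdb"):
        raise StructuralError(f"unsupported format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_atoms = ensemble.n_atoms
    atom_names = [f"X{i}" for i in range(n_atoms)]
    resindex = np.zeros(n_atoms, dtype=int)
    resnames = []
    for ri, lip in enumerate(ensemble.lipids):
        resnames.append(lip.species)
        for name, idx in lip.atoms.items():
            atom_names[idx] = name
            resindex[idx] = ri
        if lip.anchor is not None:
            resindex[lip.anchor] = ri
        for cname, idx_list in lip.chains.items():
            for k, idx in enumerate(idx_list):
                atom_names[idx] = f"{cname[0].upper()}{k + 1}"
                resindex[idx] = ri

    u = mda.Universe.empty(n_atoms, n_residues=len(ensemble.lipids),
                           atom_resindex=resindex, trajectory=True)
    u.add_TopologyAttr("names", atom_names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", [lip.lipid_id + 1 for lip in ensemble.lipids])

    paths = []
    for f in range(ensemble.n_frames):
        box = ensemble.box_for(f)
        u.atoms.positions = ensemble.coords[f] * 10.0  # nm -> A
        u.dimensions = [box[0] * 10, box[1] * 10, box[2] * 10, 90, 90, 90]
        path = out_dir / f"{prefix}_{f:05d}.{fmt}"
        u.atoms.write(str(path))
        paths.append(path)
    return paths


def write_json(obj, path) -> None:
    """Deterministic JSON artifact writer (sorted keys, stable floats)."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj
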