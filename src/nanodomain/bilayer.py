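"""Post-hoc coordinate analysis of lipid bilayer ensembles.

Metrics used to characterize how a pentameric lectin (CTxB) reorganizes
glycosphingolipids, computed from coordinate snapshots rather than by
running molecular dynamics:

* headgroup angle fluctuation: the standard deviation over time
  (sigma_theta) of the angle between headgroup-defined vectors and the
  bilayer normal, for toxin-bound versus unbound lipids;
* chain interdigitation: the time-averaged fraction of a chain's
  carbons lying past the bilayer midplane in the opposing leaflet;
* trans-bilayer coupling: inter-leaflet heavy-atom contact counts
  between chains of an upper-leaflet and a lower-leaflet species;
* area per lipid: periodic 2-D Voronoi tessellation of anchor-atom
  positions within one leaflet;
* acyl-chain order: the C-H bond order parameter
  S_CD = <(3 cos^2 theta - 1) / 2> per chain carbon, with hydrogens
  reconstructed by ideal tetrahedral geometry when absent.

Conventions: coordinates in nm; bilayer normal = +z; midplane near
z = 0 (recomputed per frame from terminal chain carbons by default);
periodic boundaries respected via the minimum-image convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree

from .errors import SchemaError, StructuralError

log = logging.getLogger(__name__)

LEAFLETS = ("upper", "lower")
TETRA_HALF_ANGLE = np.deg2rad(109.47122 / 2.0)  # half the ideal H-C-H angle


@dataclass
class Lipid:
    lipid_id: int
    species: str
    leaflet: str
    anchor: int | None = None  # atom index of the in-plane anchor
    atoms: dict = field(default_factory=dict)  # named atoms (headgroup etc.)
    chains: dict = field(default_factory=dict)  # chain name -> ordered atom indices

    def __post_init__(self):
        if self.leaflet not in LEAFLETS:
            raise SchemaError(f"lipid {self.lipid_id}: unknown leaflet {self.leaflet!r}")


@dataclass
class BilayerEnsemble:
    """Per-frame lipid coordinates with leaflet/chain/headgroup annotations."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), nm
    box: np.ndarray     # (3,) or (n_frames, 3), nm
    lipids: list

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.box = np.asarray(self.box, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructuralError("coords must have shape (n_frames, n_atoms, 3)")
        if np.any(self.box <= 0):
            raise StructuralError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def box_for(self, frame: int) -> np.ndarray:
        return self.box if self.box.ndim == 1 else self.box[frame]

    def lipids_of(self, species: str | None = None, leaflet: str | None = None) -> list:
        out = self.lipids
        if species is not None:
            out = [l for l in out if l.species == species]
        if leaflet is not None:
            out = [l for l in out if l.leaflet == leaflet]
        return out

    def species_present(self) -> set:
        return {l.species for l in self.lipids}


@dataclass(frozen=True)
class HeadgroupVectorSpec:
    """Three ordered atom-name pairs defining headgroup vectors V1-V3."""

    pairs: tuple = (("V1A", "V1B"), ("V2A", "V2B"), ("V3A", "V3B"))

    def __post_init__(self):
        if len(self.pairs) != 3:
            raise SchemaError("exactly three headgroup vectors are expected")


@dataclass
class AngleSeries:
    lipid_id: int
    vector_id: str  # "V1" | "V2" | "V3"
    theta_deg: np.ndarray  # per-frame angle to +z
    group: str  # "bound" | "unbound"


@dataclass
class SigmaThetaResult:
    table: pd.DataFrame  # columns: vector_id, group, sigma_theta, n_lipids
    ratio: float  # sigma_theta(unbound) / sigma_theta(bound), averaged over vectors
    ratio_per_vector: dict
    undefined_groups: list


@dataclass
class InterdigitationResult:
    chain: str
    species: str
    value: float
    per_frame: np.ndarray


@dataclass
class CouplingResult:
    pair_label: str
    contacts_per_frame: np.ndarray
    normalized_coupling: float  # contacts per species-a lipid per frame
    cutoff: float


@dataclass
class AreaPerLipidResult:
    leaflet: str
    per_species_mean: dict  # species -> mean area (nm^2)
    per_lipid: pd.DataFrame  # frame, lipid_id, species, area


def minimum_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary periodic cell."""
    return vec - box * np.round(vec / box)


def _atom_index(lipid: Lipid, name: str) -> int:
    if name not in lipid.atoms:
        raise SchemaError(f"lipid {lipid.lipid_id} ({lipid.species}) lacks atom {name!r}")
    return lipid.atoms[name]


def headgroup_angle_series(
    ensemble: BilayerEnsemble,
    spec: HeadgroupVectorSpec,
    bound_ids: Iterable[int],
    species: str = "GM1",
) -> list[AngleSeries]:
    """Per-frame angles between each headgroup vector and +z, per lipid.

    ``bound_ids`` marks the lipids in contact with the toxin; the rest
    of the species is the unbound group.  Vectors are built with the
    minimum-image convention so headgroups straddling a periodic
    boundary are handled correctly.
    """
    bound = set(bound_ids)
    lipids = ensemble.lipids_of(species=species)
    if not lipids:
        raise SchemaError(f"no lipids of species {species!r}")
    box = ensemble.box if ensemble.box.ndim == 2 else ensemble.box[None, :]
    series = []
    for lip in lipids:
        for k, (a_name, b_name) in enumerate(spec.pairs, start=1):
            ia, ib = _atom_index(lip, a_name), _atom_index(lip, b_name)
            v = ensemble.coords[:, ib, :] - ensemble.coords[:, ia, :]
            v = minimum_image(v, box if box.shape[0] > 1 else box[0])
            norm = np.linalg.norm(v, axis=1)
            if np.any(norm == 0):
                raise StructuralError(
                    f"zero-length headgroup vector V{k} on lipid {lip.lipid_id}"
                )
            theta = np.degrees(np.arccos(np.clip(v[:, 2] / norm, -1.0, 1.0)))
            group = "bound" if lip.lipid_id in bound else "unbound"
            series.append(AngleSeries(lip.lipid_id, f"V{k}", theta, group))
    return series


def sigma_theta(series: Sequence[AngleSeries]) -> SigmaThetaResult:
    """Angle-fluctuation summary: sample SD of theta per series, grouped.

    sigma_theta is averaged over lipids within each (vector, group);
    the bound/unbound ratio is sigma(unbound)/sigma(bound) per vector,
    then averaged.  Groups with no lipids leave the ratio undefined.
    """
    if not series:
        raise StructuralError("no angle series supplied")
    rows = []
    for s in series:
        if len(s.theta_deg) < 2:
            raise StructuralError("each angle series needs at least 2 frames")
        rows.append(
            {"vector_id": s.vector_id, "group": s.group, "lipid_id": s.lipid_id,
             "sd": float(np.std(s.theta_deg, ddof=1))}
        )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["vector_id", "group"])["sd"]
        .agg(sigma_theta="mean", n_lipids="size")
        .reset_index()
    )
    ratios, undefined = {}, []
    for vec in sorted(df["vector_id"].unique()):
        sub = agg[agg["vector_id"] == vec].set_index("group")["sigma_theta"]
        if "bound" in sub.index and "unbound" in sub.index and sub["bound"] > 0:
            ratios[vec] = float(sub["unbound"] / sub["bound"])
        else:
            missing = [g for g in ("bound", "unbound") if g not in sub.index]
            undefined.extend(f"{vec}:{g}" for g in (missing or ["bound=0"]))
            ratios[vec] = np.nan
    finite = [v for v in ratios.values() if np.isfinite(v)]
    overall = float(np.mean(finite)) if finite else np.nan
    if undefined:
        log.warning("sigma_theta ratio undefined for %s", undefined)
    return SigmaThetaResult(agg, overall, ratios, undefined)


def _midplane_per_frame(ensemble: BilayerEnsemble, midplane) -> np.ndarray:
    """z of the bilayer midplane per frame.

    Default ("terminal_com"): the z-center of mass of the terminal
    carbon of every chain of every lipid -- robust to leaflet asymmetry.
    A float fixes the midplane explicitly.
    """
    if isinstance(midplane, (int, float)):
        return np.full(ensemble.n_frames, float(midplane))
    if midplane != "terminal_com":
        raise StructuralError(f"unknown midplane convention {midplane!r}")
    idx = [chain[-1] for lip in ensemble.lipids for chain in lip.chains.values() if chain]
    if not idx:
        raise StructuralError("no chain atoms available to locate the midplane")
    return ensemble.coords[:, idx, 2].mean(axis=1)


def interdigitation_fraction(
    ensemble: BilayerEnsemble,
    species: str,
    chain: str,
    midplane="terminal_com",
) -> InterdigitationResult:
    """Fraction of chain carbons past the midplane into the opposite leaflet.

    Per frame, per lipid of ``species``: the fraction of the named
    chain's carbons with z beyond the midplane (below it for
    upper-leaflet lipids, above it for lower-leaflet ones), averaged
    over lipids and frames.  Bounded in [0, 1] and monotone in
    penetration depth.
    """
    lipids = ensemble.lipids_of(species=species)
    if not lipids:
        raise SchemaError(f"species {species!r} absent from the ensemble")
    zm = _midplane_per_frame(ensemble, midplane)
    fracs = []  # (n_frames,) per lipid
    for lip in lipids:
        if chain not in lip.chains or not lip.chains[chain]:
            raise SchemaError(f"lipid {lip.lipid_id} has no chain {chain!r}")
        z = ensemble.coords[:, lip.chains[chain], 2]  # (F, C)
        if lip.leaflet == "upper":
            beyond = z < zm[:, None]
        else:
            beyond = z > zm[:, None]
        fracs.append(beyond.mean(axis=1))
    per_frame = np.mean(fracs, axis=0)
    return InterdigitationResult(chain, species, float(per_frame.mean()), per_frame)


def transbilayer_contacts(
    ensemble: BilayerEnsemble,
    species_a: str,
    species_b: str,
    cutoff: float = 0.4,
) -> CouplingResult:
    """Inter-leaflet chain-chain contacts between two species.

    Counts, per frame, heavy-atom pairs (chain atoms of the
    upper-leaflet ``species_a`` x chain atoms of the lower-leaflet
    ``species_b``) within ``cutoff`` nm under periodic minimum-image
    distances, and normalizes per species-a lipid per frame.
    """
    if cutoff <= 0:
        raise StructuralError("cutoff must be positive")
    lip_a = ensemble.lipids_of(species=species_a, leaflet="upper")
    lip_b = ensemble.lipids_of(species=species_b, leaflet="lower")
    if not lip_a:
        raise SchemaError(f"no upper-leaflet lipids of species {species_a!r}")
    if not lip_b:
        raise SchemaError(f"no lower-leaflet lipids of species {species_b!r}")
    idx_a = [i for lip in lip_a for chain in lip.chains.values() for i in chain]
    idx_b = [i for lip in lip_b for chain in lip.chains.values() for i in chain]
    counts = np.zeros(ensemble.n_frames, dtype=np.int64)
    for f in range(ensemble.n_frames):
        box = ensemble.box_for(f)
        a = np.mod(ensemble.coords[f, idx_a, :], box)
        b = np.mod(ensemble.coords[f, idx_b, :], box)
        tree_a = cKDTree(a, boxsize=box)
        tree_b = cKDTree(b, boxsize=box)
        counts[f] = tree_a.count_neighbors(tree_b, cutoff)
    normalized = float(counts.mean() / len(lip_a))
    return CouplingResult(f"{species_a}-{species_b}", counts, normalized, cutoff)


def _polygon_area(vertices: np.ndarray) -> float:
    """Area of a convex polygon given unordered vertices (shoelace)."""
    c = vertices.mean(axis=0)
    ang = np.arctan2(vertices[:, 1] - c[1], vertices[:, 0] - c[0])
    v = vertices[np.argsort(ang)]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _voronoi_areas_periodic(xy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Per-point Voronoi cell areas on a 2-D torus via the 9-replica tiling."""
    n = len(xy)
    offsets = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)], float)
    tiles = (xy[None, :, :] + (offsets * box_xy)[:, None, :]).reshape(-1, 2)
    # put the central copy first so its indices are 0..n-1
    central_first = np.concatenate([tiles[4 * n : 5 * n], np.delete(tiles, slice(4 * n, 5 * n), axis=0)])
    vor = Voronoi(central_first)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise StructuralError("unbounded Voronoi cell; degenerate configuration")
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


def area_per_lipid(
    ensemble: BilayerEnsemble,
    leaflet: str,
    frames: Sequence[int] | None = None,
) -> AreaPerLipidResult:
    """Voronoi area per lipid within one leaflet.

    Anchor-atom (x, y) positions of every lipid in the leaflet are
    tessellated with periodic ghost replicas; cell areas sum to the box
    area (checked to 1e-6 relative on every frame).  Coincident anchors
    are perturbed by 1e-6 nm with a warning.
    """
    if leaflet not in LEAFLETS:
        raise StructuralError(f"unknown leaflet {leaflet!r}")
    lipids = ensemble.lipids_of(leaflet=leaflet)
    if len(lipids) < 3:
        raise StructuralError("area per lipid needs at least 3 lipids in the leaflet")
    for lip in lipids:
        if lip.anchor is None:
            raise SchemaError(f"lipid {lip.lipid_id} has no anchor atom")
    frame_list = range(ensemble.n_frames) if frames is None else frames
    anchor_idx = [lip.anchor for lip in lipids]
    rows = []
    means: dict = {}
    for f in frame_list:
        box = ensemble.box_for(f)
        box_xy = box[:2]
        xy = np.mod(ensemble.coords[f, anchor_idx, :2], box_xy)
        tree = cKDTree(xy, boxsize=box_xy)
        close = tree.query_pairs(1e-9, output_type="ndarray")
        if len(close):
            log.warning("frame %s: %d coincident anchors perturbed by 1e-6 nm", f, len(close))
            for k, (i, j) in enumerate(close):
                xy[j] += 1e-6 * np.array([np.cos(k + 1.0), np.sin(k + 1.0)])
            xy = np.mod(xy, box_xy)
        areas = _voronoi_areas_periodic(xy, box_xy)
        box_area = float(box_xy[0] * box_xy[1])
        rel = abs(areas.sum() - box_area) / box_area
        if rel > 1e-6:
            raise StructuralError(
                f"Voronoi areas sum to {areas.sum():.8g}, box area {box_area:.8g} "
                f"(relative error {rel:.2e})"
            )
        for lip, a in zip(lipids, areas):
            rows.append({"frame": f, "lipid_id": lip.lipid_id,
                         "species": lip.species, "area": a})
    per_lipid = pd.DataFrame(rows)
    per_species = per_lipid.groupby("species")["area"].mean().to_dict()
    return AreaPerLipidResult(leaflet, per_species, per_lipid)


def scd_from_vectors(ch_vectors: np.ndarray) -> float:
    """Order parameter <(3 cos^2 theta - 1)/2> of C-H unit vectors vs +z."""
    v = np.asarray(ch_vectors, float)
    norm = np.linalg.norm(v, axis=-1)
    cos = v[..., 2] / norm
    return float(np.nanmean(1.5 * cos ** 2 - 0.5))


def reconstruct_ch_vectors(prev: np.ndarray, curr: np.ndarray, nxt: np.ndarray,
                           box: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ideal-tetrahedral C-H unit vectors at ``curr`` from its chain neighbors.

    The two hydrogens lie in the plane spanned by the C-C-C bisector and
    the normal to the C-C-C plane, at half the ideal H-C-H angle on
    either side of the bisector.  Collinear carbon triples leave NaN
    vectors (no defined plane).
    """
    a = minimum_image(prev - curr, box)
    b = minimum_image(nxt - curr, box)
    ah = a / np.linalg.norm(a, axis=-1, keepdims=True)
    bh = b / np.linalg.norm(b, axis=-1, keepdims=True)
    u = np.cross(ah, bh)
    un = np.linalg.norm(u, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(un > 1e-12, u / un, np.nan)
    bis = -(ah + bh)
    bn = np.linalg.norm(bis, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        bis = np.where(bn > 1e-12, bis / bn, np.nan)
    h1 = np.cos(TETRA_HALF_ANGLE) * bis + np.sin(TETRA_HALF_ANGLE) * u
    h2 = np.cos(TETRA_HALF_ANGLE) * bis - np.sin(TETRA_HALF_ANGLE) * u
    return h1, h2


def chain_order_parameter(
    ensemble: BilayerEnsemble, species: str, chain: str
) -> pd.DataFrame:
    """Per-carbon S_CD profile for one chain of one species.

    Hydrogens are reconstructed from heavy-atom geometry (ideal
    tetrahedral construction from three consecutive chain carbons), so
    the profile covers interior carbons 2..C-1.  S_CD = -0.5 for chains
    perfectly aligned with the normal, 0 for isotropic orientations.
    """
    lipids = ensemble.lipids_of(species=species)
    if not lipids:
        raise SchemaError(f"species {species!r} absent from the ensemble")
    n_carbons = len(lipids[0].chains.get(chain, []))
    if n_carbons < 3:
        raise StructuralError(f"chain {chain!r} must have at least 3 carbons")
    box = ensemble.box if ensemble.box.ndim == 1 else ensemble.box[0]
    profile = []
    for k in range(1, n_carbons - 1):
        vals = []
        for lip in lipids:
            idx = lip.chains[chain]
            if len(idx) != n_carbons:
                raise SchemaError(
                    f"lipid {lip.lipid_id}: chain {chain!r} length differs across lipids"
                )
            prev = ensemble.coords[:, idx[k - 1], :]
            curr = ensemble.coords[:, idx[k], :]
            nxt = ensemble.coords[:, idx[k + 1], :]
            h1, h2 = reconstruct_ch_vectors(prev, curr, nxt, box)
            cos = np.concatenate([h1[:, 2], h2[:, 2]])  # unit vectors by construction
            vals.append(1.5 * cos ** 2 - 0.5)
        profile.append({"carbon": k + 1, "s_cd": float(np.nanmean(np.concatenate(vals)))})
    return pd.DataFrame(profile)
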