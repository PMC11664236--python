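"""File formats, schema validation and reproducibility manifests.

CSV dialect: UTF-8, comma-separated, header row, decimal point. Column
names are normalised case-insensitively through an alias table so that
minor naming variants of deposited tables load without code changes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

TRAIT_COLUMNS = [
    "eye_surface_area",
    "facet_number",
    "facet_diameter",
    "radius_of_curvature",
    "io_angle",
    "eye_parameter",
    "monocular_fov",
    "binocular_overlap",
    "central_ocellus_diameter",
    "lateral_ocelli_diameter",
    "ocellar_alignment",
]

#: alias -> canonical column name, matched after lowercasing and stripping
#: spaces/underscores; extend freely for new table layouts
COLUMN_ALIASES = {
    "species": "species",
    "specimen": "specimen",
    "specimenid": "specimen",
    "id": "specimen",
    "itd": "itd",
    "intertegulardistance": "itd",
    "bodysize": "itd",
    "eyesurfacearea": "eye_surface_area",
    "eyesurface": "eye_surface_area",
    "surfacearea": "eye_surface_area",
    "cornealarea": "eye_surface_area",
    "facetnumber": "facet_number",
    "nfacets": "facet_number",
    "facetcount": "facet_number",
    "facetdiameter": "facet_diameter",
    "facetdiam": "facet_diameter",
    "radiusofcurvature": "radius_of_curvature",
    "curvature": "radius_of_curvature",
    "radius": "radius_of_curvature",
    "ioangle": "io_angle",
    "interommatidialangle": "io_angle",
    "eyeparameter": "eye_parameter",
    "monocularfov": "monocular_fov",
    "fov": "monocular_fov",
    "binocularoverlap": "binocular_overlap",
    "overlap": "binocular_overlap",
    "centralocellusdiameter": "central_ocellus_diameter",
    "centralocellus": "central_ocellus_diameter",
    "lateralocellidiameter": "lateral_ocelli_diameter",
    "lateralocelli": "lateral_ocelli_diameter",
    "ocellaralignment": "ocellar_alignment",
    "alignment": "ocellar_alignment",
}

#: plausible-unit ranges for warnings (value outside -> probably wrong units)
RANGE_CHECKS = {
    "itd": (1.0, 10.0),  # mm
    "facet_diameter": (5.0, 100.0),  # um
    "io_angle": (0.1, 10.0),  # degrees
    "eye_parameter": (0.05, 5.0),  # um rad
    "monocular_fov": (0.0, 100.0),
    "binocular_overlap": (0.0, 100.0),
    "ocellar_alignment": (0.0, 180.0),
}


class SchemaError(ValueError):
    """An input table does not match its expected schema."""


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = col.strip().lower().replace(" ", "").replace("_", "").replace("-", "")
        mapping[col] = COLUMN_ALIASES.get(key, col.strip().lower())
    return df.rename(columns=mapping)


def read_trait_table(
    path: str | Path,
    require_all_traits: bool = True,
    dialect: str = "standard",
) -> pd.DataFrame:
    """Load a species/specimen visual-trait table.

    Requires ``species``, ``itd`` and (by default) the 11 trait columns;
    a ``specimen`` column is optional. Values outside plausible-unit ranges
    trigger warnings naming the row — a common symptom of radians-vs-degrees
    or mm-vs-um mistakes.
    """
    kwargs = {"sep": ";", "decimal": ","} if dialect == "semicolon" else {}
    df = _normalise_columns(pd.read_csv(path, **kwargs))
    required = ["species", "itd"] + (TRAIT_COLUMNS if require_all_traits else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"trait table {path} is missing columns {missing}; expected names: "
            f"{['species', 'itd', 'specimen'] + TRAIT_COLUMNS}"
        )
    for col, (lo, hi) in RANGE_CHECKS.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(vals < lo) | (vals > hi)]
        if len(bad):
            warnings.warn(
                f"column '{col}' outside plausible range [{lo}, {hi}] in rows "
                f"{list(bad[:5])} — check units",
                stacklevel=2,
            )
    return df


def read_inventory(path: str | Path, dialect: str = "standard") -> pd.DataFrame:
    """Load a long-format (site, species, year, count) inventory."""
    kwargs = {"sep": ";", "decimal": ","} if dialect == "semicolon" else {}
    df = _normalise_columns(pd.read_csv(path, **kwargs))
    required = ["site", "species", "year", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"inventory {path} is missing columns {missing}")
    dup = df.duplicated(subset=["site", "species", "year"])
    if dup.any():
        raise SchemaError(
            f"inventory {path} has duplicate (site, species, year) records at rows "
            f"{list(df.index[dup][:5])}"
        )
    return df


def read_environment(path: str | Path, dialect: str = "standard") -> pd.DataFrame:
    """Load the per-site environment table (tree cover, floral, lat/lon, elev)."""
    kwargs = {"sep": ";", "decimal": ","} if dialect == "semicolon" else {}
    df = _normalise_columns(pd.read_csv(path, **kwargs))
    aliases = {
        "treecover": "tree_cover_pct",
        "treecoverpct": "tree_cover_pct",
        "tree_cover_pct": "tree_cover_pct",
        "floralresource": "floral_resource_permille",
        "floralresourcepermille": "floral_resource_permille",
        "floral_resource_permille": "floral_resource_permille",
        "latitude": "lat",
        "lat": "lat",
        "longitude": "lon",
        "lon": "lon",
        "elevation": "elev_m",
        "elevm": "elev_m",
        "elev_m": "elev_m",
        "site": "site",
    }
    ren = {}
    for col in df.columns:
        key = col.strip().lower().replace("_", "").replace(" ", "")
        ren[col] = aliases.get(key, col)
    df = df.rename(columns=ren)
    required = ["site", "tree_cover_pct", "floral_resource_permille", "lat", "lon", "elev_m"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"environment table {path} is missing columns {missing}")
    tc = df["tree_cover_pct"]
    if ((tc < 0) | (tc > 100)).any():
        raise SchemaError("tree cover must be within [0, 100] %")
    return df


def read_newick(path: str | Path) -> pd.DataFrame:
    """Parse a Newick tree into a Brownian-expectation correlation matrix.

    Under Brownian motion the trait covariance of two tips is the shared
    root-to-MRCA path length; the correlation divides by the geometric mean
    of the two root-to-tip depths. An ultrametric tree therefore gives
    ``depth(MRCA) / tree depth``.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises assorted parse error types
        raise SchemaError(f"malformed Newick file {path}: {exc}") from exc
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    depth = {t.label: tree.find_node_with_taxon_label(t.label).root_distance for t in taxa}
    n = len(taxa)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mrca = pdm.mrca(taxa[i], taxa[j])
            shared = mrca.root_distance if mrca is not None else 0.0
            corr[i, j] = corr[j, i] = shared / np.sqrt(depth[labels[i]] * depth[labels[j]])
    return pd.DataFrame(corr, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# meshes and point clouds


def write_ply(path: str | Path, vertices: np.ndarray, triangles: np.ndarray) -> None:
    """Write an ASCII PLY triangle mesh."""
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(triangles)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_ply(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ASCII PLY triangle mesh written by :func:`write_ply`."""
    with open(path, encoding="utf-8") as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise SchemaError(f"{path} is not a PLY file")
        n_vert = n_face = 0
        while True:
            line = fh.readline()
            if not line:
                raise SchemaError(f"{path}: unexpected end of header")
            line = line.strip()
            if line.startswith("format") and "ascii" not in line:
                raise SchemaError(f"{path}: only ASCII PLY is supported")
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.array(
            [fh.readline().split()[:3] for _ in range(n_vert)], dtype=float
        )
        faces = np.array(
            [fh.readline().split()[1:4] for _ in range(n_face)], dtype=int
        )
    return verts, faces


def read_facet_centres(path: str | Path) -> np.ndarray:
    """Read a facet-centre CSV with header (id,x,y,z)."""
    df = _normalise_columns(pd.read_csv(path))
    for c in ("x", "y", "z"):
        if c not in df.columns:
            raise SchemaError(f"facet-centre file {path} needs columns id,x,y,z")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def write_facet_centres(path: str | Path, centres: np.ndarray) -> None:
    pd.DataFrame(centres, columns=["x", "y", "z"]).rename_axis("id").to_csv(path)


# ---------------------------------------------------------------------------
# reports, config, manifests


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_report(obj: dict, path: str | Path) -> None:
    """Write a JSON report (lossless round-trip for plain dict content)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


@dataclass
class StudyConfig:
    """Resolved configuration of a full pipeline run."""

    inventory: Path
    environment: Path
    traits: Path
    out_dir: Path
    phylogeny: Path | None = None
    alias_map: Path | None = None
    seed: int = 0
    n_imputation_draws: int = 30
    n_common_species: int = 12
    include_relative: bool = True
    trait_names: tuple[str, ...] = ()
    extras: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        known = {}
        for key in ("inventory", "environment", "traits", "phylogeny", "alias_map", "out_dir"):
            if key in raw:
                known[key] = base / raw.pop(key)
        for key in (
            "seed",
            "n_imputation_draws",
            "n_common_species",
            "include_relative",
            "trait_names",
        ):
            if key in raw:
                known[key] = raw.pop(key)
        if "trait_names" in known:
            known["trait_names"] = tuple(known["trait_names"])
        cfg = cls(extras=raw, **known)
        for key in ("inventory", "environment", "traits"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path '{key}' does not exist: {p}")
        if not isinstance(cfg.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        return cfg


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, inputs: dict[str, str | Path], config: dict) -> Path:
    """Record input hashes, config and versions for byte-reproducibility."""
    import beevision

    manifest = {
        "inputs": {name: {"path": str(p), "sha256": file_sha256(p)} for name, p in inputs.items()},
        "config": config,
        "versions": {
            "beevision": beevision.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    out = Path(out_dir) / "manifest.json"
    write_report(manifest, out)
    return out
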