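"""Scene-bundle and table I/O.

A scene bundle on disk is three text files:

* ``particles.csv`` — scene_id, x_nm, y_nm, channel, size_class_nm, face
* ``rois.geojson``  — FeatureCollection with top-level ``"units": "nm"``;
  one feature per polygon with properties ``scene_id`` and ``role``
  (``psd`` for demarcated IMP clusters and ``pface`` for background
  regions) plus the scene's group metadata on the psd feature
* ``scenes.json``   — run provenance (tool version, seed, preset,
  resolved options) and per-scene metadata

plus optional rendered images (8-bit grayscale TIFF/PNG).  Every
analysis output embeds the resolved configuration, so a run can be
reproduced from its own files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry import mapping, shape

from . import __version__
from .geometry import Polygon
from .synthetic import ParticleRecord, Point, PreEmbedProfile, SynapseScene

PARTICLE_COLUMNS = ["scene_id", "x_nm", "y_nm", "channel", "size_class_nm", "face"]


class BundleFormatError(ValueError):
    """Raised for malformed or inconsistent scene bundles."""


@dataclass
class RunConfig:
    """Resolved parameters embedded in every output for provenance."""

    seed: int | None = None
    preset: str | None = None
    rim_nm: float = 30.0
    glun1_min: int = 3
    imp_min: int = 30
    eps_mem_nm: float = 25.0
    px_size_nm: float = 0.5
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["tool"] = f"frlquant {__version__}"
        return d


def write_scene_bundle(
    scenes: list[SynapseScene], outdir: str | Path, config: RunConfig | None = None
) -> Path:
    """Write particles.csv, rois.geojson and scenes.json for a scene list."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for sc in scenes:
        for p in sc.particles:
            rows.append(
                dict(
                    scene_id=sc.scene_id,
                    x_nm=p.position.x,
                    y_nm=p.position.y,
                    channel=p.channel,
                    size_class_nm=p.size_class,
                    face=p.face,
                )
            )
    pd.DataFrame(rows, columns=PARTICLE_COLUMNS).to_csv(
        outdir / "particles.csv", index=False
    )

    features = []
    for sc in scenes:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(sc.true_polygon.shapely),
                "properties": {
                    "scene_id": sc.scene_id,
                    "role": "psd",
                    "genotype": sc.genotype,
                    "age_months": sc.age_months,
                    "compartment": sc.compartment,
                    "animal_id": sc.animal_id,
                    "complete": sc.complete,
                    "n_imp": int(np.asarray(sc.imp_points).shape[0]),
                },
            }
        )
        if sc.pface_region is not None and not sc.pface_region.is_empty:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(sc.pface_region),
                    "properties": {"scene_id": sc.scene_id, "role": "pface"},
                }
            )
    geojson = {
        "type": "FeatureCollection",
        "units": "nm",
        "features": features,
    }
    (outdir / "rois.geojson").write_text(json.dumps(geojson))

    meta = {
        "config": (config or RunConfig()).as_dict(),
        "n_scenes": len(scenes),
        "scenes": [
            {
                "scene_id": sc.scene_id,
                "genotype": sc.genotype,
                "age_months": sc.age_months,
                "compartment": sc.compartment,
                "animal_id": sc.animal_id,
                "complete": sc.complete,
                "n_imp": int(np.asarray(sc.imp_points).shape[0]),
                **{k: v for k, v in sc.meta.items() if _jsonable(v)},
            }
            for sc in scenes
        ],
    }
    (outdir / "scenes.json").write_text(json.dumps(meta, indent=1))
    return outdir


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None)))


def read_scene_bundle(indir: str | Path) -> list[SynapseScene]:
    """Read and validate a scene bundle written by :func:`write_scene_bundle`
    (or assembled by hand in the same formats).

    Raises :class:`BundleFormatError` on missing unit metadata, malformed
    geometry, or particles referencing unknown scenes.  IMP point sets are
    not stored in bundles; the demarcated polygon's vertices stand in for
    them (they are exactly the outermost IMPs), so re-demarcation of a
    round-tripped bundle is idempotent.
    """
    indir = Path(indir)
    pfile, rfile = indir / "particles.csv", indir / "rois.geojson"
    if not pfile.exists() or not rfile.exists():
        raise BundleFormatError(f"bundle at {indir} needs particles.csv and rois.geojson")
    particles = pd.read_csv(pfile)
    missing = set(PARTICLE_COLUMNS) - set(particles.columns)
    if missing:
        raise BundleFormatError(f"particles.csv missing columns: {sorted(missing)}")
    gj = json.loads(rfile.read_text())
    if gj.get("units") != "nm":
        raise BundleFormatError('rois.geojson must declare top-level "units": "nm"')

    psd: dict[int, dict] = {}
    pface: dict[int, _ShapelyPolygon] = {}
    for feat in gj.get("features", []):
        props = feat.get("properties", {})
        sid = props.get("scene_id")
        if sid is None:
            raise BundleFormatError("feature without scene_id")
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise BundleFormatError(f"scene {sid}: malformed geometry: {exc}") from exc
        if not geom.is_valid:
            raise BundleFormatError(f"scene {sid}: invalid geometry")
        if props.get("role") == "pface":
            pface[sid] = geom
        else:
            psd[sid] = {"geom": geom, "props": props}

    known = set(psd)
    dangling = sorted(set(particles["scene_id"].unique()) - known)
    if dangling:
        raise BundleFormatError(f"particles reference unknown scene_id(s): {dangling}")

    scenes = []
    for sid in sorted(psd):
        entry = psd[sid]
        props = entry["props"]
        poly = Polygon(np.asarray(entry["geom"].exterior.coords[:-1]))
        rows = particles[particles["scene_id"] == sid]
        precs = [
            ParticleRecord(
                Point(float(r.x_nm), float(r.y_nm)),
                int(r.size_class_nm),
                str(r.channel),
                str(r.face),
            )
            for r in rows.itertuples()
        ]
        scenes.append(
            SynapseScene(
                scene_id=int(sid),
                imp_points=poly.xy,
                true_polygon=poly,
                particles=precs,
                complete=bool(props.get("complete", True)),
                pface_region=pface.get(sid, _ShapelyPolygon()),
                genotype=str(props.get("genotype", "NA")),
                age_months=int(props.get("age_months", 0)),
                compartment=str(props.get("compartment", "NA")),
                animal_id=int(props.get("animal_id", 0)),
                meta=(
                    {"imp_count": int(props["n_imp"])} if "n_imp" in props else {}
                ),
            )
        )
    return scenes


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None):
    """Write a CSV with a single provenance header line (prefix ``#``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "# " + json.dumps((config or RunConfig()).as_dict(), sort_keys=True)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_preembed_bundle(
    profiles: list[PreEmbedProfile], outdir: str | Path, config: RunConfig | None = None
) -> Path:
    """Membrane outlines as GeoJSON (units nm) + particle CSV per cell."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    feats = []
    for pr in profiles:
        for x, y in pr.particles:
            rows.append(dict(cell_id=pr.cell_id, x_nm=float(x), y_nm=float(y)))
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(_ShapelyPolygon(pr.membrane)),
                "properties": {
                    "cell_id": pr.cell_id,
                    "animal_id": pr.animal_id,
                    "genotype": pr.genotype,
                    "compartment": pr.compartment,
                },
            }
        )
    pd.DataFrame(rows, columns=["cell_id", "x_nm", "y_nm"]).to_csv(
        outdir / "preembed_particles.csv", index=False
    )
    (outdir / "profiles.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "units": "nm", "features": feats})
    )
    (outdir / "preembed.json").write_text(
        json.dumps({"config": (config or RunConfig()).as_dict(), "n_cells": len(profiles)})
    )
    return outdir


def read_preembed_bundle(indir: str | Path) -> list[PreEmbedProfile]:
    indir = Path(indir)
    particles = pd.read_csv(indir / "preembed_particles.csv")
    gj = json.loads((indir / "profiles.geojson").read_text())
    if gj.get("units") != "nm":
        raise BundleFormatError('profiles.geojson must declare "units": "nm"')
    profiles = []
    for feat in gj["features"]:
        props = feat["properties"]
        cid = int(props["cell_id"])
        geom = shape(feat["geometry"])
        rows = particles[particles["cell_id"] == cid]
        profiles.append(
            PreEmbedProfile(
                cell_id=cid,
                animal_id=int(props.get("animal_id", 0)),
                genotype=str(props.get("genotype", "NA")),
                compartment=str(props.get("compartment", "NA")),
                membrane=np.asarray(geom.exterior.coords[:-1]),
                particles=rows[["x_nm", "y_nm"]].to_numpy(dtype=float),
            )
        )
    return profiles
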