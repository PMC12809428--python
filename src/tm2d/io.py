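"""File formats: MRC2014 volumes/micrographs, PDB atom lists, particle
tables (CSV), result-map bundles and an experimental STAR pose export.

Coordinate conventions in tables: positions are 0-based ``(x, y)`` pixels
with x the fast image axis; Euler angles are intrinsic ZYZ degrees; defocus
offsets are in angstroms with positive = underfocus.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import asdict
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from ._exceptions import MrcFormatError, ParameterError
from .containers import Micrograph, VolumeGrid
from .filters import CTFParams
from .match import MatchResultMaps, ParticleRecord
from .scattering import AtomRecord

__all__ = [
    "read_mrc",
    "write_mrc",
    "read_pdb_atoms",
    "read_atoms_csv",
    "write_atoms_csv",
    "particles_to_dataframe",
    "dataframe_to_particles",
    "write_particles_csv",
    "read_particles_csv",
    "write_result_maps",
    "read_result_maps",
    "read_ctf_csv",
    "write_star",
]

PARTICLE_SCHEMA_VERSION = "1"
PARTICLE_COLUMNS = ["micrograph_id", "x", "y", "phi", "theta", "psi",
                    "defocus", "z_score", "fp_probability", "flag"]

_SUPPORTED_MRC_MODES = {0, 1, 2, 6}


# ---------------------------------------------------------------------------
# MRC
# ---------------------------------------------------------------------------


def _peek_mrc_mode(path: Path) -> int:
    with open(path, "rb") as fh:
        head = fh.read(1024)
    if len(head) < 1024:
        raise MrcFormatError(f"{path}: file shorter than an MRC header")
    mode = struct.unpack("<i", head[12:16])[0]
    if mode not in _SUPPORTED_MRC_MODES:
        swapped = struct.unpack(">i", head[12:16])[0]
        if swapped in _SUPPORTED_MRC_MODES:
            return swapped
        raise MrcFormatError(
            f"{path}: unsupported MRC mode {mode}; supported modes are "
            f"{sorted(_SUPPORTED_MRC_MODES)}")
    return mode


def read_mrc(path, pixel_size: float | None = None) -> VolumeGrid | Micrograph:
    """Read an MRC2014 file; returns a `Micrograph` when nz == 1, else a
    `VolumeGrid`. The pixel size comes from the header cell unless
    overridden; a zero header pixel size requires an explicit override."""
    path = Path(path)
    _peek_mrc_mode(path)
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)  # axes (u=x, v=y, w=z)
    spacing = float(m.grid.spacing[0])
    if pixel_size is None:
        if not spacing > 0:  # catches 0 and NaN from a zeroed cell
            raise MrcFormatError(
                f"{path}: header pixel size is 0; pass pixel_size=... explicitly")
        pixel_size = spacing
    if arr.ndim == 3 and arr.shape[2] == 1:
        return Micrograph(data=arr[:, :, 0].T.astype(np.float32), pixel_size=pixel_size)
    return VolumeGrid(data=arr.T.astype(np.float32), pixel_size=pixel_size)


def write_mrc(path, obj: VolumeGrid | Micrograph | np.ndarray,
              pixel_size: float | None = None) -> None:
    """Write a volume or micrograph as 32-bit real MRC2014 with the pixel
    size in the header cell."""
    if isinstance(obj, (VolumeGrid, Micrograph)):
        data, px = obj.data, obj.pixel_size
    else:
        data = np.asarray(obj, dtype=np.float32)
        if pixel_size is None:
            raise ParameterError("pixel_size required when writing a bare array")
        px = pixel_size
    if data.ndim == 2:
        arr = np.ascontiguousarray(data.T.astype(np.float32)[:, :, None])
    elif data.ndim == 3:
        arr = np.ascontiguousarray(data.T.astype(np.float32))
    else:
        raise ParameterError("only 2D or 3D data can be written")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    m.grid.unit_cell = gemmi.UnitCell(
        arr.shape[0] * px, arr.shape[1] * px, arr.shape[2] * px, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Atom lists
# ---------------------------------------------------------------------------


def read_pdb_atoms(path, exclude_h: bool = False) -> list[AtomRecord]:
    """ATOM/HETATM records from a text PDB file.

    Element symbols come from columns 77-78 (gemmi falls back to the atom
    name when absent). Blank occupancy fields default to 1.0 with a warning.
    Malformed fixed-width records raise with the offending line number.
    """
    path = Path(path)
    blank_occ = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ParameterError(
                    f"{path}:{lineno}: truncated ATOM/HETATM record "
                    f"(needs at least coordinates through column 54)")
            if len(line) < 60 or not line[54:60].strip():
                blank_occ += 1
    if blank_occ:
        warnings.warn(f"{path}: {blank_occ} atom(s) with blank occupancy; using 1.0")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParameterError(f"{path}: failed to parse PDB: {exc}") from exc
    atoms: list[AtomRecord] = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    el = at.element.name
                    if exclude_h and el in ("H", "D"):
                        continue
                    occ = at.occ if at.occ > 0 else 1.0
                    atoms.append(AtomRecord(
                        element=el,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        b_factor=max(at.b_iso, 0.0),
                        occupancy=min(occ, 1.0),
                    ))
        break  # first model only
    return atoms


def read_atoms_csv(path) -> list[AtomRecord]:
    """Minimal CSV dialect for synthetic fixtures: element,x,y,z,b,occ."""
    df = pd.read_csv(path, comment="#")
    need = {"element", "x", "y", "z", "b", "occ"}
    if not need.issubset(df.columns):
        raise ParameterError(f"atom CSV needs columns {sorted(need)}")
    return [AtomRecord(r.element, (r.x, r.y, r.z), r.b, r.occ)
            for r in df.itertuples()]


def write_atoms_csv(path, atoms) -> None:
    rows = [{"element": a.element, "x": a.position[0], "y": a.position[1],
             "z": a.position[2], "b": a.b_factor, "occ": a.occupancy}
            for a in atoms]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Particle tables
# ---------------------------------------------------------------------------


def particles_to_dataframe(records: list[ParticleRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=PARTICLE_COLUMNS)


def dataframe_to_particles(df: pd.DataFrame) -> list[ParticleRecord]:
    out = []
    for r in df.itertuples():
        out.append(ParticleRecord(
            micrograph_id=str(r.micrograph_id), x=int(r.x), y=int(r.y),
            phi=float(r.phi), theta=float(r.theta), psi=float(r.psi),
            defocus=float(r.defocus), z_score=float(r.z_score),
            fp_probability=float(r.fp_probability),
            flag=str(getattr(r, "flag", "") or ""),
        ))
    return out


def write_particles_csv(path, records: list[ParticleRecord] | pd.DataFrame,
                        provenance: dict | None = None) -> None:
    """Particle table with a commented provenance header (schema version,
    package version, optional config hash); losslessly re-ingestable."""
    from . import __version__
    df = records if isinstance(records, pd.DataFrame) else particles_to_dataframe(records)
    with open(path, "w") as fh:
        fh.write(f"# tm2d_particles schema_version={PARTICLE_SCHEMA_VERSION} "
                 f"package_version={__version__}\n")
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_particles_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns and c != "flag"]
    if missing:
        raise ParameterError(f"particle CSV missing columns {missing}")
    if "flag" not in df.columns:
        df["flag"] = ""
    df["flag"] = df["flag"].fillna("")
    return df


# ---------------------------------------------------------------------------
# Result-map bundles
# ---------------------------------------------------------------------------


def write_result_maps(maps: MatchResultMaps, outdir, prefix: str = "") -> None:
    """All named per-pixel maps as MRC plus a JSON sidecar with the scalar
    metadata needed to reload them for refinement/constrained searches."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in maps.named_maps().items():
        write_mrc(outdir / f"{prefix}{name}.mrc", arr.astype(np.float32),
                  pixel_size=maps.pixel_size)
    meta = {
        "n_total": maps.n_total, "n_per_pixel": maps.n_per_pixel,
        "template_box": maps.template_box, "pixel_size": maps.pixel_size,
        "tail_counts": {str(k): v for k, v in maps.tail_counts.items()},
    }
    (outdir / f"{prefix}meta.json").write_text(json.dumps(meta, indent=1))


def read_result_maps(outdir, prefix: str = "") -> MatchResultMaps:
    outdir = Path(outdir)
    meta_path = outdir / f"{prefix}meta.json"
    if not meta_path.exists():
        raise ParameterError(
            f"missing result-map bundle in {outdir}: expected {meta_path.name} and "
            "the map MRC files written by a prior match run")
    meta = json.loads(meta_path.read_text())
    arrays = {}
    for name in ("mip", "scaled_mip", "best_phi", "best_theta", "best_psi",
                 "best_defocus", "corr_mean", "corr_variance"):
        p = outdir / f"{prefix}{name}.mrc"
        if not p.exists():
            raise ParameterError(f"missing result map {p}")
        arrays[name] = read_mrc(p, pixel_size=meta["pixel_size"]).data.astype(np.float64)
    return MatchResultMaps(
        **arrays,
        n_total=int(meta["n_total"]), n_per_pixel=int(meta["n_per_pixel"]),
        template_box=int(meta["template_box"]), pixel_size=float(meta["pixel_size"]),
        tail_counts={float(k): int(v) for k, v in meta.get("tail_counts", {}).items()},
    )


# ---------------------------------------------------------------------------
# CTF tables and STAR export
# ---------------------------------------------------------------------------


def read_ctf_csv(path, pixel_size: float | None = None) -> list[CTFParams]:
    """Per-micrograph CTF parameters from CSV with columns voltage, cs,
    amplitude_contrast, defocus_u, defocus_v and optionally astig_angle,
    phase_shift, b_factor, pixel_size (CTF estimation itself is upstream)."""
    df = pd.read_csv(path, comment="#")
    need = {"voltage", "cs", "amplitude_contrast", "defocus_u", "defocus_v"}
    if not need.issubset(df.columns):
        raise ParameterError(f"CTF CSV needs columns {sorted(need)}")
    out = []
    for r in df.to_dict("records"):
        out.append(CTFParams(
            voltage=r["voltage"], cs=r["cs"],
            amplitude_contrast=r["amplitude_contrast"],
            defocus_u=r["defocus_u"], defocus_v=r["defocus_v"],
            astig_angle=r.get("astig_angle", 0.0),
            phase_shift=r.get("phase_shift", 0.0),
            b_factor=r.get("b_factor", 0.0),
            pixel_size=r.get("pixel_size", pixel_size or 1.0),
        ))
    return out


def write_star(path, records: list[ParticleRecord] | pd.DataFrame,
               pixel_size: float = 1.0) -> None:
    """Experimental STAR pose export for external reconstruction packages.

    Angles are written as rlnAngleRot/Tilt/Psi from this package's intrinsic
    ZYZ (phi, theta, psi) convention; verify handedness against the
    consuming package before relying on reconstructions.
    """
    df = records if isinstance(records, pd.DataFrame) else particles_to_dataframe(records)
    cols = ["rlnMicrographName", "rlnCoordinateX", "rlnCoordinateY",
            "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi",
            "rlnDefocusU", "rlnDefocusV"]
    with open(path, "w") as fh:
        fh.write("# Experimental pose export. Euler convention: intrinsic ZYZ\n"
                 "# (phi,theta,psi) mapped to (rot,tilt,psi); positive defocus\n"
                 "# = underfocus; coordinates in pixels at pixel size "
                 f"{pixel_size} A.\n\ndata_particles\n\nloop_\n")
        for i, c in enumerate(cols, start=1):
            fh.write(f"_{c} #{i}\n")
        for r in df.itertuples():
            fh.write(f"{r.micrograph_id} {r.x:.1f} {r.y:.1f} "
                     f"{r.phi:.4f} {r.theta:.4f} {r.psi:.4f} "
                     f"{r.defocus:.1f} {r.defocus:.1f}\n")
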