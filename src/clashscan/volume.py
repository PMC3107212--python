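"""Molecular volumes and overlap volumes by two independent methods.

SES_GRID: solvent-excluded volume on a voxel grid. Atom spheres are inflated
by the probe radius; the region a probe center can reach from outside is
found by connected-component labelling, and the solvent region is that set
dilated back by the probe radius (a morphological closing of the van der
Waals union). Voxels not reachable by solvent, including interior cavities,
count as molecular volume. Deterministic.

SAS_MC: the volume enclosed by the solvent-accessible surface, i.e. the
union of spheres of radius r_i + probe, estimated by Monte-Carlo sampling
over the bounding box. Deterministic for a fixed seed; a standard error is
reported alongside.

The overlap of two molecules R and S is V(R) + V(S) - V(R u S), the volume
occupied by both at once. For SES_GRID the three volumes are computed on a
single common grid; for SAS_MC a single sample cloud classifies membership
in R and S, so the overlap identity holds exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from clashscan.structio import StructureModel

logger = logging.getLogger(__name__)

SES_GRID = "SES_GRID"
SAS_MC = "SAS_MC"


@dataclass(frozen=True)
class VolumeMethod:
    name: str  # SES_GRID or SAS_MC
    probe_radius: float = 1.5
    grid_spacing: float = 0.5  # SES_GRID only
    n_samples: int = 2_000_000  # SAS_MC only
    seed: int = 1337  # SAS_MC only

    def __post_init__(self):
        if self.name not in (SES_GRID, SAS_MC):
            raise ValueError(f"unknown method {self.name!r}")
        if self.probe_radius < 0 or self.grid_spacing <= 0 or self.n_samples <= 0:
            raise ValueError("invalid volume-method parameters")


def ses_method(probe_radius: float = 1.5, grid_spacing: float = 0.5) -> VolumeMethod:
    return VolumeMethod(SES_GRID, probe_radius=probe_radius, grid_spacing=grid_spacing)


def sas_method(probe_radius: float = 1.4, n_samples: int = 2_000_000,
               seed: int = 1337) -> VolumeMethod:
    return VolumeMethod(SAS_MC, probe_radius=probe_radius, n_samples=n_samples, seed=seed)


@dataclass(frozen=True)
class OverlapMeasurement:
    method: str
    v_r: float
    v_s: float
    v_union: float
    overlap: float
    stderr: Optional[float] = None  # SAS_MC overlap standard error


def _gather(models: Sequence[StructureModel] | StructureModel) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(models, StructureModel):
        models = [models]
    centers: List[np.ndarray] = []
    radii: List[float] = []
    for model in models:
        for _, _, atom in model.iter_atoms():
            if atom.vdw_radius is None:
                raise ValueError("vdW radii must be assigned before volume computation")
            centers.append(atom.position)
            radii.append(atom.vdw_radius)
    if not centers:
        return np.empty((0, 3)), np.empty((0,))
    return np.asarray(centers, dtype=float), np.asarray(radii, dtype=float)


# ---------------------------------------------------------------------------
# SES on a voxel grid


class _Grid:
    """Axis-aligned voxel grid; voxel centers at origin + (i + 0.5) * spacing."""

    def __init__(self, lo: np.ndarray, hi: np.ndarray, spacing: float, margin: float):
        self.spacing = spacing
        self.origin = lo - margin
        self.shape = np.ceil((hi + margin - self.origin) / spacing).astype(int)

    def stamp_field(self, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
        """Per-voxel max of (r_i - distance to center i): positive inside the union.

        Voxels farther than any sphere keep a large negative value.
        """
        field = np.full(self.shape, -4.0 * self.spacing)
        sp = self.spacing
        for c, r in zip(centers, radii):
            reach = r + 2 * sp
            lo_idx = np.maximum(np.floor((c - reach - self.origin) / sp - 0.5).astype(int), 0)
            hi_idx = np.minimum(np.ceil((c + reach - self.origin) / sp - 0.5).astype(int) + 1,
                                self.shape)
            if np.any(lo_idx >= hi_idx):
                continue
            ax = [self.origin[k] + (np.arange(lo_idx[k], hi_idx[k]) + 0.5) * sp - c[k]
                  for k in range(3)]
            d = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                        + ax[2][None, None, :] ** 2)
            sub = field[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
            np.maximum(sub, r - d, out=sub)
        return field

    def partial_volume(self, signed_field: np.ndarray) -> float:
        """Volume of the region where the field is positive, with the boundary
        voxels weighted by their estimated coverage (first-order antialiasing)."""
        w = np.clip(0.5 + signed_field / self.spacing, 0.0, 1.0)
        return float(w.sum()) * self.voxel_volume

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3


def _ses_signed_field(grid: _Grid, centers: np.ndarray, radii: np.ndarray,
                      probe: float) -> np.ndarray:
    """Signed field positive inside the solvent-excluded region."""
    if probe == 0.0:
        return grid.stamp_field(centers, radii)
    inflated = grid.stamp_field(centers, radii + probe) >= 0.0
    # probe centers reachable from outside the box
    free = ~inflated
    labels, _ = ndimage.label(free)
    border = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
    border = border[border != 0]
    accessible = np.isin(labels, border)
    # solvent = accessible probe centers dilated back by the probe radius;
    # voxels deeper than the probe radius from any accessible point are molecular
    dist = ndimage.distance_transform_edt(~accessible, sampling=grid.spacing)
    return dist - probe


def volume_ses_grid(models: Sequence[StructureModel] | StructureModel,
                    method: Optional[VolumeMethod] = None) -> float:
    """Solvent-excluded volume (A^3) of the union of the given models."""
    method = method or ses_method()
    centers, radii = _gather(models)
    if centers.size == 0:
        logger.warning("SES volume of empty atom set is 0")
        return 0.0
    grid = _make_grid(centers, radii, method)
    return grid.partial_volume(_ses_signed_field(grid, centers, radii, method.probe_radius))


def _make_grid(centers: np.ndarray, radii: np.ndarray, method: VolumeMethod) -> _Grid:
    margin = radii.max() + 2 * method.probe_radius + 3 * method.grid_spacing
    return _Grid(centers.min(axis=0), centers.max(axis=0), method.grid_spacing, margin)


# ---------------------------------------------------------------------------
# SAS volume by Monte Carlo


class _SphereSet:
    """Membership tests against a union of spheres, grouped by radius."""

    def __init__(self, centers: np.ndarray, radii: np.ndarray, probe: float):
        self.groups = []
        for r in np.unique(radii):
            pts = centers[radii == r]
            self.groups.append((cKDTree(pts), r + probe))
        self.lo = (centers - (radii + probe)[:, None]).min(axis=0)
        self.hi = (centers + (radii + probe)[:, None]).max(axis=0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        inside = np.zeros(len(points), dtype=bool)
        for tree, r in self.groups:
            todo = ~inside
            if not todo.any():
                break
            d, _ = tree.query(points[todo], k=1)
            inside[todo] = d <= r
        return inside


def volume_sas_mc(models: Sequence[StructureModel] | StructureModel,
                  method: Optional[VolumeMethod] = None) -> Tuple[float, float]:
    """Monte-Carlo solvent-accessible volume (A^3) and its standard error."""
    method = method or sas_method()
    centers, radii = _gather(models)
    if centers.size == 0:
        logger.warning("SAS volume of empty atom set is 0")
        return 0.0, 0.0
    spheres = _SphereSet(centers, radii, method.probe_radius)
    rng = np.random.default_rng(method.seed)
    pts = rng.uniform(spheres.lo, spheres.hi, size=(method.n_samples, 3))
    inside = spheres.contains(pts)
    box = float(np.prod(spheres.hi - spheres.lo))
    p = inside.mean()
    volume = p * box
    stderr = box * math.sqrt(p * (1.0 - p) / method.n_samples)
    return float(volume), float(stderr)


# ---------------------------------------------------------------------------
# Overlap


def overlap_volume(model_r: StructureModel, model_s: StructureModel,
                   method: VolumeMethod) -> OverlapMeasurement:
    """Overlap volume V(R) + V(S) - V(R u S) of two already-superposed models."""
    if method.name == SES_GRID:
        cr, rr = _gather(model_r)
        cs, rs = _gather(model_s)
        call = np.vstack([cr, cs]) if cr.size and cs.size else (cr if cr.size else cs)
        rall = np.concatenate([rr, rs])
        grid = _make_grid(call, rall, method)
        probe = method.probe_radius
        v_r = grid.partial_volume(_ses_signed_field(grid, cr, rr, probe)) if cr.size else 0.0
        v_s = grid.partial_volume(_ses_signed_field(grid, cs, rs, probe)) if cs.size else 0.0
        v_union = grid.partial_volume(_ses_signed_field(grid, call, rall, probe))
        raw = v_r + v_s - v_union
        if raw < 0:
            logger.info("clamping slightly negative SES overlap %.3f to 0", raw)
        return OverlapMeasurement(SES_GRID, v_r, v_s, v_union, max(raw, 0.0))

    cr, rr = _gather(model_r)
    cs, rs = _gather(model_s)
    set_r = _SphereSet(cr, rr, method.probe_radius) if cr.size else None
    set_s = _SphereSet(cs, rs, method.probe_radius) if cs.size else None
    los = [s.lo for s in (set_r, set_s) if s]
    his = [s.hi for s in (set_r, set_s) if s]
    if not los:
        return OverlapMeasurement(SAS_MC, 0.0, 0.0, 0.0, 0.0, 0.0)
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    rng = np.random.default_rng(method.seed)
    pts = rng.uniform(lo, hi, size=(method.n_samples, 3))
    in_r = set_r.contains(pts) if set_r else np.zeros(len(pts), bool)
    in_s = set_s.contains(pts) if set_s else np.zeros(len(pts), bool)
    box = float(np.prod(hi - lo))
    n = method.n_samples
    p_and = (in_r & in_s).mean()
    v_r = float(in_r.mean() * box)
    v_s = float(in_s.mean() * box)
    v_union = float((in_r | in_s).mean() * box)
    overlap = float(p_and * box)
    stderr = box * math.sqrt(p_and * (1.0 - p_and) / n)
    return OverlapMeasurement(SAS_MC, v_r, v_s, v_union, overlap, float(stderr))


def passes_overlap_filter(m_ses: OverlapMeasurement, m_sas: OverlapMeasurement,
                          threshold: float = 2000.0) -> bool:
    """True iff both methods report an overlap of at least ``threshold`` A^3."""
    return m_ses.overlap >= threshold and m_sas.overlap >= threshold
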