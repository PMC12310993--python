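"""Perfusion probability maps and majority-territory maps over a cohort.

Given co-registered per-patient territory label volumes (voxel grids in a
common template space), the probability that artery ``i`` perfuses voxel
``x`` is P_i(x) = N_{x,i} / sum_{j in S} N_{x,j} with S = {MCA, ACA, PCA},
where N_{x,i} counts patients whose map predicts artery i to perfuse x.
Voxels perfused by fewer than ``min_count`` patients, or outside a
template mask, are excluded.  The majority map assigns each retained
voxel to the artery with the highest probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabelVolume",
    "ProbabilityMap",
    "probability_map",
    "majority_map",
    "overlap_table",
    "load_label_volume",
    "save_label_volume",
    "MAJOR_ARTERIES",
]

MAJOR_ARTERIES = ("MCA", "ACA", "PCA")
DEFAULT_CODES = {"none": 0, "MCA": 1, "ACA": 2, "PCA": 3}


@dataclass
class LabelVolume:
    """Integer voxel label grid with named codes.

    ``multi`` optionally carries per-artery boolean membership grids for
    patients whose map allows one voxel to be perfused by several arteries
    (overlap territories); when absent, membership is exclusive from
    ``data``.
    """

    data: np.ndarray  # 3D integer grid
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    codes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CODES))
    multi: dict[str, np.ndarray] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be a 3D grid")

    def membership(self, artery: str) -> np.ndarray:
        """Boolean grid: does this patient's map perfuse each voxel by ``artery``."""
        if self.multi is not None and artery in self.multi:
            return np.asarray(self.multi[artery], bool)
        return self.data == self.codes[artery]


@dataclass
class ProbabilityMap:
    probabilities: dict[str, np.ndarray]  # artery -> float grid
    support: np.ndarray  # sum_j N_{x,j}
    retained: np.ndarray  # bool grid
    min_count: int
    arteries: tuple = MAJOR_ARTERIES


def probability_map(
    cohort: list[LabelVolume],
    min_count: int = 10,
    mask: LabelVolume | np.ndarray | None = None,
    arteries=MAJOR_ARTERIES,
    exclusive: bool = False,
) -> ProbabilityMap:
    """Cohort voxelwise perfusion probabilities P_i = N_{x,i} / sum_j N_{x,j}.

    ``exclusive=True`` ignores any multi-artery membership grids and counts
    each patient's exclusive label only.
    """
    if not cohort:
        raise ValueError("empty cohort")
    shape = cohort[0].data.shape
    for k, vol in enumerate(cohort):
        if vol.data.shape != shape:
            raise ValueError(f"cohort member {k} has shape {vol.data.shape}, "
                             f"expected {shape}")
    if min_count > len(cohort):
        import warnings

        warnings.warn(f"min_count={min_count} exceeds cohort size {len(cohort)}: "
                      "every voxel will be excluded", stacklevel=2)

    counts = {}
    for artery in arteries:
        n = np.zeros(shape, dtype=np.int64)
        for vol in cohort:
            if exclusive:
                n += vol.data == vol.codes[artery]
            else:
                n += vol.membership(artery)
        counts[artery] = n
    support = sum(counts.values())
    retained = support >= min_count
    if mask is not None:
        mask_arr = mask.data if isinstance(mask, LabelVolume) else np.asarray(mask)
        retained &= mask_arr.astype(bool)
    probs = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for artery in arteries:
            p = counts[artery] / support
            p[~retained] = np.nan
            probs[artery] = p
    return ProbabilityMap(probs, support, retained, min_count, tuple(arteries))


def majority_map(pmap: ProbabilityMap,
                 codes: dict[str, int] | None = None) -> tuple[LabelVolume, np.ndarray]:
    """Assign each retained voxel to the artery of highest probability.

    Ties go to the first artery in the declared order (MCA, ACA, PCA) and
    are returned as a boolean tie grid alongside the map; excluded voxels
    get the "none" code.
    """
    codes = codes or dict(DEFAULT_CODES)
    stack = np.stack([pmap.probabilities[a] for a in pmap.arteries])
    with np.errstate(invalid="ignore"):
        winner = np.nanargmax(np.where(np.isnan(stack), -np.inf, stack), axis=0)
    best = np.max(np.where(np.isnan(stack), -np.inf, stack), axis=0)
    n_at_max = np.sum(stack == best[None], axis=0)
    tie = pmap.retained & (n_at_max > 1)
    out = np.full(pmap.retained.shape, codes["none"], dtype=np.int64)
    for k, artery in enumerate(pmap.arteries):
        out[pmap.retained & (winner == k)] = codes[artery]
    return LabelVolume(out, codes=codes), tie


def overlap_table(
    map_a: LabelVolume, map_b: LabelVolume, labels=MAJOR_ARTERIES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-normalized percentage confusion between two territory maps.

    Voxels unlabeled ("none") in either map are excluded.  Returns the
    A->B table (of voxels labeled ``l`` in A, the percentage carrying each
    label in B) and the B->A table.
    """
    if map_a.data.shape != map_b.data.shape:
        raise ValueError("maps must share a voxel grid")
    in_a = np.isin(map_a.data, [map_a.codes[l] for l in labels])
    in_b = np.isin(map_b.data, [map_b.codes[l] for l in labels])
    both = in_a & in_b
    if not np.any(both):
        raise ValueError("maps have no labeled voxels in common")

    def one_direction(src: LabelVolume, dst: LabelVolume) -> pd.DataFrame:
        rows = {}
        for la in labels:
            sel = both & (src.data == src.codes[la])
            total = sel.sum()
            rows[la] = {
                lb: 100.0 * np.sum(sel & (dst.data == dst.codes[lb])) / total
                if total else np.nan
                for lb in labels
            }
        return pd.DataFrame(rows).T[list(labels)]

    return one_direction(map_a, map_b), one_direction(map_b, map_a)


# ---------------------------------------------------------------------- I/O
def load_label_volume(path: str | Path,
                      codes: dict[str, int] | None = None) -> LabelVolume:
    """Read a NIfTI label volume (pre-registered to the template space)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(data, zooms, codes or dict(DEFAULT_CODES),
                       affine=np.asarray(img.affine))


def save_label_volume(vol: LabelVolume, path: str | Path) -> None:
    import nibabel as nib

    affine = vol.affine if vol.affine is not None else np.diag(
        list(vol.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.int16), affine), str(path))
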