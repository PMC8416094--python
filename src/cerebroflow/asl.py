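"""ASL perfusion quantification against a vascular territory atlas.

Implements the non-selective pipeline (label/control subtraction, territory
perfusion splits) and the vessel-selective pipeline (labeling-efficiency
scaling, voxelwise fractional-blood-supply maps, robust territory statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateSignalError, FormatError, GridMismatchError

TERRITORY_LABELS: Dict[int, str] = {
    1: "RACA",
    2: "LACA",
    3: "RMCA",
    4: "LMCA",
    5: "RPCA",
    6: "LPCA",
    7: "Cerebellum",
}
TERRITORY_NAMES: Tuple[str, ...] = tuple(TERRITORY_LABELS[i] for i in range(1, 8))
NECK_ARTERY_ORDER: Tuple[str, ...] = ("RICA", "RVA", "LVA", "LICA")


@dataclass
class PerfusionVolume:
    """3-D perfusion-signal image (arbitrary units) on a fixed grid."""

    voxels: np.ndarray
    affine: np.ndarray = None  # type: ignore[assignment]
    voxel_volume_mm3: float = 1.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError("perfusion volume must be 3-D")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("perfusion volume contains non-finite values")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def shape(self):
        return self.voxels.shape

    def same_grid_as(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class TerritoryAtlas:
    """Integer label image: 0 background, 1..7 vascular territories."""

    labels: np.ndarray
    affine: np.ndarray = None  # type: ignore[assignment]
    territory_names: Dict[int, str] = field(default_factory=lambda: dict(TERRITORY_LABELS))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("atlas labels must be an integer array")
        if self.labels.ndim != 3:
            raise FormatError("atlas must be 3-D")
        present = set(np.unique(self.labels).tolist())
        allowed = set(range(0, 8))
        if not present <= allowed:
            raise FormatError(f"atlas labels outside 0..7: {sorted(present - allowed)}")
        for lab, name in self.territory_names.items():
            if not np.any(self.labels == lab):
                raise FormatError(f"territory {name} (label {lab}) is empty")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def shape(self):
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class TerritoryArteryMap:
    """Territory -> [(intracranial artery, share)] with shares summing to 1."""

    mapping: Dict[str, List[Tuple[str, float]]] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.mapping is None:
            self.mapping = {
                "RACA": [("RACA", 1.0)],
                "LACA": [("LACA", 1.0)],
                "RMCA": [("RMCA", 1.0)],
                "LMCA": [("LMCA", 1.0)],
                "RPCA": [("RPCA", 1.0)],
                "LPCA": [("LPCA", 1.0)],
                "Cerebellum": [("RSCA", 0.5), ("LSCA", 0.5)],
            }
        for terr, shares in self.mapping.items():
            total = sum(w for _, w in shares)
            if abs(total - 1.0) > 1e-12:
                raise FormatError(f"shares for territory {terr} sum to {total}, not 1")

    def arteries_of(self, territory: str) -> List[Tuple[str, float]]:
        return self.mapping[territory]

    @property
    def all_arteries(self) -> List[str]:
        out: List[str] = []
        for shares in self.mapping.values():
            for a, _ in shares:
                if a not in out:
                    out.append(a)
        return out


@dataclass
class PerfusionSplit:
    """Fraction of whole-brain perfusion signal per territory (sums to 1)."""

    ps: Dict[str, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.ps[t] for t in TERRITORY_NAMES])


@dataclass
class VSASLStudy:
    """Vessel-selective acquisitions: one volume + labeling efficiency per neck artery."""

    volumes: Dict[str, PerfusionVolume]
    efficiencies: Dict[str, float]

    def __post_init__(self):
        missing = [a for a in NECK_ARTERY_ORDER if a not in self.volumes]
        if missing:
            raise FormatError(f"VS-ASL study missing neck arteries: {missing}")
        for a in NECK_ARTERY_ORDER:
            eff = self.efficiencies.get(a)
            if eff is None or not (0.0 < eff <= 1.0):
                raise FormatError(f"labeling efficiency for {a} must be in (0, 1]")


@dataclass
class FBSTable:
    """Territories x neck-arteries fractional blood supply.

    ``median`` holds the central value per cell; ``mad`` the median absolute
    deviation (NaN for noise-free model sources).  ``source`` is one of
    'asl', 'transport', 'particles'.
    """

    median: pd.DataFrame
    mad: Optional[pd.DataFrame]
    source: str

    def __post_init__(self):
        if self.source not in ("asl", "transport", "particles"):
            raise ValueError(f"unknown FBS source {self.source!r}")

    @property
    def territories(self) -> List[str]:
        return list(self.median.index)

    @property
    def arteries(self) -> List[str]:
        return list(self.median.columns)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for terr in self.territories:
            for art in self.arteries:
                rows.append(
                    {
                        "territory": terr,
                        "artery": art,
                        "value": self.median.loc[terr, art],
                        "mad": (
                            self.mad.loc[terr, art] if self.mad is not None else np.nan
                        ),
                        "source": self.source,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "FBSTable":
        source = df["source"].iloc[0]
        med = df.pivot(index="territory", columns="artery", values="value")
        mad = df.pivot(index="territory", columns="artery", values="mad")
        if mad.isna().all().all():
            mad = None
        return cls(median=med, mad=mad, source=source)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def subtract_and_average(
    labels: Sequence[np.ndarray], controls: Sequence[np.ndarray], affine=None,
    voxel_volume_mm3: float = 1.0,
) -> PerfusionVolume:
    """Voxelwise mean over pairs of (control - label)."""
    if len(labels) != len(controls) or len(labels) == 0:
        raise FormatError(
            f"need equal nonzero counts of label/control images, got "
            f"{len(labels)}/{len(controls)}"
        )
    shape = np.asarray(labels[0]).shape
    for img in list(labels) + list(controls):
        if np.asarray(img).shape != shape:
            raise GridMismatchError("label/control images are not on one grid")
    acc = np.zeros(shape, dtype=float)
    for lab, ctl in zip(labels, controls):
        acc += np.asarray(ctl, dtype=float) - np.asarray(lab, dtype=float)
    return PerfusionVolume(
        voxels=acc / len(labels), affine=affine, voxel_volume_mm3=voxel_volume_mm3
    )


def perfusion_splits(perf: PerfusionVolume, atlas: TerritoryAtlas) -> PerfusionSplit:
    """Territory share of the whole-brain perfusion integral.

    The whole brain is the union of the seven atlas territories (background is
    excluded from both numerator and denominator).
    """
    if perf.shape != atlas.shape:
        raise GridMismatchError(
            f"perfusion grid {perf.shape} != atlas grid {atlas.shape}"
        )
    total = float(perf.voxels[atlas.brain_mask].sum())
    if total == 0.0:
        raise DegenerateSignalError("whole-brain perfusion integral is zero")
    ps = {}
    for lab, name in atlas.territory_names.items():
        ps[name] = float(perf.voxels[atlas.mask(lab)].sum()) / total
    return PerfusionSplit(ps=ps)


def scale_by_efficiency(study: VSASLStudy) -> Dict[str, PerfusionVolume]:
    """Divide each artery's VS-ASL volume by its labeling efficiency."""
    scaled = {}
    for artery in NECK_ARTERY_ORDER:
        eff = study.efficiencies[artery]
        vol = study.volumes[artery]
        scaled[artery] = PerfusionVolume(
            voxels=vol.voxels / eff,
            affine=vol.affine,
            voxel_volume_mm3=vol.voxel_volume_mm3,
        )
    return scaled


TOTAL_FLOOR_REL = 1e-9


def fbs_maps(
    scaled: Dict[str, PerfusionVolume],
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Voxelwise FBS maps: each scaled volume over the sum of all four.

    Returns (maps, valid_mask).  Voxels whose total perfusion magnitude falls
    below ``TOTAL_FLOOR_REL * max|total|`` are masked invalid, not divided.
    """
    arts = list(NECK_ARTERY_ORDER)
    ref = scaled[arts[0]]
    for a in arts[1:]:
        if not scaled[a].same_grid_as(ref):
            raise GridMismatchError("scaled VS-ASL volumes are not on one grid")
    total = np.zeros(ref.shape)
    for a in arts:
        total += scaled[a].voxels
    floor = TOTAL_FLOOR_REL * float(np.max(np.abs(total))) if np.any(total) else np.inf
    valid = np.abs(total) >= floor
    maps = {}
    for a in arts:
        m = np.full(ref.shape, np.nan)
        np.divide(scaled[a].voxels, total, out=m, where=valid)
        maps[a] = m
    return maps, valid


def _median_mad(values: np.ndarray) -> Tuple[float, float]:
    m = float(np.median(values))
    return m, float(np.median(np.abs(values - m)))


def territory_fbs_stats(
    maps: Dict[str, np.ndarray],
    atlas: TerritoryAtlas,
    valid: Optional[np.ndarray] = None,
) -> FBSTable:
    """Median and MAD of each FBS map over each atlas territory.

    Negative voxel values (ASL noise) are retained.  A (territory, artery)
    cell with no valid voxels is reported as NaN.
    """
    ref_shape = atlas.shape
    for a, m in maps.items():
        if m.shape != ref_shape:
            raise GridMismatchError(f"FBS map {a} grid mismatch with atlas")
    if valid is None:
        valid = np.ones(ref_shape, dtype=bool)
    med = pd.DataFrame(
        index=list(TERRITORY_NAMES), columns=list(NECK_ARTERY_ORDER), dtype=float
    )
    mad = med.copy()
    for lab, terr in atlas.territory_names.items():
        sel = atlas.mask(lab) & valid
        for artery in NECK_ARTERY_ORDER:
            vals = maps[artery][sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                med.loc[terr, artery] = np.nan
                mad.loc[terr, artery] = np.nan
            else:
                m, d = _median_mad(vals)
                med.loc[terr, artery] = m
                mad.loc[terr, artery] = d
    return FBSTable(median=med, mad=mad, source="asl")


def asl_fbs_table(study: VSASLStudy, atlas: TerritoryAtlas) -> FBSTable:
    """Full VS-ASL pipeline: scale, divide voxelwise, summarize per territory."""
    scaled = scale_by_efficiency(study)
    maps, valid = fbs_maps(scaled)
    return territory_fbs_stats(maps, atlas, valid)
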