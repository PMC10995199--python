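"""Per-object morphometry and cell-level morphology classification.

Each binarised cytoplasmic fluorescent object gets two statistics:

* **Box-count fractal dimension D** — the negative slope of an ordinary
  least-squares fit of ``log N(eps)`` against ``log eps``, where ``N(eps)``
  counts the eps-by-eps grid boxes (grid anchored at the object's bounding
  box origin) containing at least one foreground pixel.  Thin elongated
  filaments approach D ~ 1, space-filling blobs D ~ 2, and objects smaller
  than every box size give D = 0.
* **Perimeter** — boundary length in µm, by default the count of exposed
  pixel edges of the 4-connected object (each unit step scaled by the pixel
  size); a Crofton estimate is available as an alternative.

Cells are then classified by majority vote of their objects: `filamented`
when most objects meet or exceed the D threshold (default 0.7), and
`longer` when most object perimeters meet or exceed the perimeter threshold
(default 10 µm).  Equal counts — including cells without objects — are ties
and are excluded from downstream percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "MorphometryConfig",
    "FluorObject",
    "CellClassification",
    "box_count_dimension",
    "object_perimeter",
    "classify_cell_by_D",
    "classify_cell_by_perimeter",
    "measure_objects",
    "classify_cells",
]

DEFAULT_BOX_SIZES = (2, 3, 4, 6, 8, 12, 16, 32, 64)


@dataclass
class MorphometryConfig:
    box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES
    d_threshold: float = 0.7
    perimeter_threshold_um: float = 10.0
    pixel_size_um: float = 0.3
    perimeter_method: str = "steps"  # "steps" (edge count) or "crofton"

    def __post_init__(self) -> None:
        bs = tuple(int(b) for b in self.box_sizes)
        if len(bs) < 3 or any(b < 2 for b in bs) or list(bs) != sorted(set(bs)):
            raise ValueError("box_sizes must be >= 3 strictly increasing ints >= 2")
        self.box_sizes = bs
        if self.d_threshold <= 0 or self.perimeter_threshold_um <= 0:
            raise ValueError("thresholds must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.perimeter_method not in ("steps", "crofton"):
            raise ValueError("perimeter_method must be 'steps' or 'crofton'")


@dataclass
class FluorObject:
    """One measured cytoplasmic object."""

    object_id: int
    cell_id: int
    d: float
    perimeter_um: float
    area_px: int
    d_flagged: bool = False  # bounding box smaller than the third box size


@dataclass
class CellClassification:
    cell_id: int
    d_class: str            # filamented | punctuated | tie
    perimeter_class: str    # longer | shorter | tie
    n_objects: int


# ---------------------------------------------------------------------------
# per-object statistics
# ---------------------------------------------------------------------------


def box_counts(mask: np.ndarray, box_sizes) -> np.ndarray:
    """N(eps) for each box size, grid anchored at the mask's bounding box."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    crop = mask[r0 : r1 + 1, c0 : c1 + 1]
    counts = []
    for eps in box_sizes:
        h = -(-crop.shape[0] // eps) * eps
        w = -(-crop.shape[1] // eps) * eps
        padded = np.zeros((h, w), dtype=bool)
        padded[: crop.shape[0], : crop.shape[1]] = crop
        blocks = padded.reshape(h // eps, eps, w // eps, eps)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    return np.asarray(counts)


def box_count_dimension(
    mask: np.ndarray, config: MorphometryConfig | None = None
) -> tuple[float, bool]:
    """Box-count fractal dimension of a binary mask.

    Returns ``(D, flagged)``; ``flagged`` is True when the bounding box is
    smaller than the third box size, i.e. most sizes see the object as a
    single box and the slope rests on few informative points.  Box sizes
    larger than the object are retained (they count one box), so an object
    confined to one box at every size has D = 0 exactly.
    """
    cfg = config or MorphometryConfig()
    n = box_counts(mask, cfg.box_sizes)
    log_eps = np.log(np.asarray(cfg.box_sizes, dtype=float))
    log_n = np.log(n.astype(float))
    slope = np.polyfit(log_eps, log_n, 1)[0]
    d = float(-slope)
    mask = np.asarray(mask, dtype=bool)
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    bbox_max = max(
        int(np.ptp(np.where(rows)[0])) + 1,
        int(np.ptp(np.where(cols)[0])) + 1,
    )
    flagged = bbox_max < cfg.box_sizes[2]
    # a zero slope can come out as -0.0
    return d + 0.0, bool(flagged)


def object_perimeter(
    mask: np.ndarray, pixel_size_um: float, method: str = "steps"
) -> float:
    """Object boundary length in µm.

    ``steps`` counts exposed pixel edges of the 4-connected object (a 1-px
    object has 4 unit steps; an n-by-n square has 4n); ``crofton`` uses the
    4-direction Crofton estimate.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if method == "steps":
        padded = np.pad(mask, 1)
        steps = 0
        for axis in (0, 1):
            steps += int(np.sum(np.diff(padded.astype(np.int8), axis=axis) != 0))
        return steps * pixel_size_um
    if method == "crofton":
        return float(measure.perimeter_crofton(mask, directions=4)) * pixel_size_um
    raise ValueError("method must be 'steps' or 'crofton'")


# ---------------------------------------------------------------------------
# cell-level classification
# ---------------------------------------------------------------------------


def classify_cell_by_D(objects, config: MorphometryConfig | None = None) -> str:
    """Majority vote over objects: D >= threshold counts as filament-like."""
    cfg = config or MorphometryConfig()
    ds = [o.d for o in objects]
    hi = sum(d >= cfg.d_threshold for d in ds)
    lo = len(ds) - hi
    if hi > lo:
        return "filamented"
    if lo > hi:
        return "punctuated"
    return "tie"


def classify_cell_by_perimeter(
    objects, config: MorphometryConfig | None = None
) -> str:
    """Majority vote: perimeter >= threshold counts as a long object."""
    cfg = config or MorphometryConfig()
    ps = [o.perimeter_um for o in objects]
    long_ = sum(p >= cfg.perimeter_threshold_um for p in ps)
    short = len(ps) - long_
    if long_ > short:
        return "longer"
    if short > long_:
        return "shorter"
    return "tie"


# ---------------------------------------------------------------------------
# convenience over segmentation output
# ---------------------------------------------------------------------------


def measure_objects(object_masks, config: MorphometryConfig | None = None):
    """Measure a list of segmentation ``ObjectMask``es into FluorObjects."""
    cfg = config or MorphometryConfig()
    out = []
    for om in object_masks:
        d, flagged = box_count_dimension(om.mask, cfg)
        per = object_perimeter(om.mask, cfg.pixel_size_um, cfg.perimeter_method)
        out.append(
            FluorObject(
                object_id=om.object_id,
                cell_id=om.cell_id,
                d=d,
                perimeter_um=per,
                area_px=int(om.area),
                d_flagged=flagged,
            )
        )
    return out


def classify_cells(
    fluor_objects, cell_ids=None, config: MorphometryConfig | None = None
):
    """Group measured objects by cell and apply both majority-vote rules.

    ``cell_ids`` optionally lists every cell in the image so that cells
    without any detected object are still emitted (as ties).
    """
    cfg = config or MorphometryConfig()
    by_cell: dict[int, list] = {}
    for o in fluor_objects:
        by_cell.setdefault(o.cell_id, []).append(o)
    ids = sorted(set(by_cell) | set(cell_ids or []))
    return [
        CellClassification(
            cell_id=cid,
            d_class=classify_cell_by_D(by_cell.get(cid, []), cfg),
            perimeter_class=classify_cell_by_perimeter(by_cell.get(cid, []), cfg),
            n_objects=len(by_cell.get(cid, [])),
        )
        for cid in ids
    ]
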