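"""Synthetic data generation: micrographs, toy protomers, assay datasets.

Everything the analysis pipeline consumes can be generated here with known
ground truth, so every downstream stage is testable without external data.

*Micrographs* emulate a two-channel high-content acquisition of cells
expressing a fluorescently tagged filament-forming enzyme: a nuclear-stain
channel with one disc per nucleus, and a reporter channel in which each
cell's cytoplasm carries either elongated, gently curved filament-like
objects (drawn as thick quadratic-Bezier polylines) or small punctate
objects (filled discs), at a controlled filamented fraction per condition.
A faint nuclear ghost is drawn in the reporter channel, mimicking the
diffuse reporter signal that makes nuclei visible in the transfection
channel.  Gaussian read noise is added to both channels.

*Toy protomers* are reproducible rigid point clouds with distinct pairwise
distances, used as substrates for helical-geometry round-trips.

*Assay datasets* draw noisy responses from the forward models in
:mod:`filaquant.binding` at stated ground-truth parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw

from . import binding
from .helix import StructureModel

__all__ = [
    "ImageSimConfig",
    "GroundTruthLabel",
    "AssaySimConfig",
    "SimulatedImage",
    "generate_cell_image",
    "generate_image_set",
    "make_toy_protomer",
    "generate_assay_dataset",
    "write_image",
]


@dataclass
class ImageSimConfig:
    """Geometry and intensity settings for one simulated field of view.

    Lengths are in µm; intensities are arbitrary units.  ``frac_filamented``
    is applied deterministically: exactly ``round-half-up(n_cells * frac)``
    cells are filamented.  The same seed gives bit-identical output.
    """

    width: int = 640
    height: int = 640
    pixel_size_um: float = 0.3
    n_cells: int = 25
    frac_filamented: float = 0.5
    filament_length_um: tuple[float, float] = (8.0, 16.0)
    filament_thickness_um: tuple[float, float] = (0.6, 1.0)
    filament_curvature: tuple[float, float] = (0.05, 0.25)
    filaments_per_cell: tuple[int, int] = (2, 4)
    puncta_diameter_um: tuple[float, float] = (0.6, 1.2)
    puncta_per_cell: tuple[int, int] = (3, 8)
    nucleus_radius_um: tuple[float, float] = (3.0, 4.5)
    cell_extent_um: float = 15.0      # cytoplasmic placement radius
    background_level: float = 0.1
    signal_level: float = 1.0
    nuclear_ghost: float = 0.3        # nucleus brightness in reporter channel
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_filamented <= 1.0):
            raise ValueError("frac_filamented must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruthLabel:
    cell_id: int
    true_class: str                   # "filamented" | "punctuated"
    nucleus_centroid: tuple[float, float]  # (row, col) px
    object_count: int


@dataclass
class SimulatedImage:
    """One simulated field with its ground-truth rasters."""

    nuclear: np.ndarray
    reporter: np.ndarray
    labels: list[GroundTruthLabel]
    nucleus_mask: np.ndarray          # ground-truth nucleus raster
    object_mask: np.ndarray           # ground-truth drawn-object raster

    def __iter__(self):
        return iter((self.nuclear, self.reporter, self.labels))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _place_nuclei(cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid placement with non-overlap by construction.

    Cells occupy a grid with a pitch of at least twice the cell extent; if
    the requested count does not fit the field at that density an explicit
    error is raised.
    """
    if cfg.n_cells == 0:
        return np.empty((0, 2))
    extent_px = cfg.cell_extent_um / cfg.pixel_size_um
    g_cols = int(np.ceil(np.sqrt(cfg.n_cells * cfg.width / cfg.height)))
    g_rows = int(np.ceil(cfg.n_cells / g_cols))
    pitch_r = cfg.height / g_rows
    pitch_c = cfg.width / g_cols
    if min(pitch_r, pitch_c) < 2 * extent_px:
        density = cfg.n_cells / (
            (cfg.width * cfg.pixel_size_um) * (cfg.height * cfg.pixel_size_um)
        )
        raise ValueError(
            f"cannot place {cfg.n_cells} non-overlapping cells of extent "
            f"{cfg.cell_extent_um} um in a "
            f"{cfg.width * cfg.pixel_size_um:.0f} x "
            f"{cfg.height * cfg.pixel_size_um:.0f} um field "
            f"(density {density:.4f} cells/um^2 too high)"
        )
    slots = [(i, j) for i in range(g_rows) for j in range(g_cols)]
    order = rng.permutation(len(slots))[: cfg.n_cells]
    jitter_r = max(0.0, pitch_r / 2 - extent_px)
    jitter_c = max(0.0, pitch_c / 2 - extent_px)
    centres = []
    for idx in order:
        i, j = slots[idx]
        r = (i + 0.5) * pitch_r + rng.uniform(-jitter_r, jitter_r)
        c = (j + 0.5) * pitch_c + rng.uniform(-jitter_c, jitter_c)
        centres.append((r, c))
    return np.asarray(centres)


def _stamp_disc(mask: np.ndarray, centre, radius_px: float) -> None:
    rr, cc = draw.disk(centre, max(radius_px, 0.6), shape=mask.shape)
    mask[rr, cc] = True


def _stamp_filament(
    mask: np.ndarray,
    centre,
    nuc_r_px: float,
    cfg: ImageSimConfig,
    rng: np.random.Generator,
) -> None:
    """A thick quadratic-Bezier polyline in the cytoplasmic annulus.

    The curve is anchored tangentially at a radius between the nucleus rim
    and the cell extent, bending outward, so filaments stay off the nucleus
    and inside the cell's footprint.
    """
    px = cfg.pixel_size_um
    extent = cfg.cell_extent_um / px
    length = rng.uniform(*cfg.filament_length_um) / px
    thick = rng.uniform(*cfg.filament_thickness_um) / px
    curv = rng.uniform(*cfg.filament_curvature)
    rho_min = nuc_r_px + thick / 2 + 8.0
    rho_max = max(
        rho_min + 1.0,
        np.sqrt(max(extent**2 - (length / 2) ** 2, 0.0)) - curv * length - 1.0,
    )
    rho = rng.uniform(rho_min, rho_max)
    phi = rng.uniform(0, 2 * np.pi)
    radial = np.array([np.sin(phi), np.cos(phi)])
    start = np.asarray(centre) + rho * radial
    tilt = rng.uniform(-0.25, 0.25)
    ct, st = np.cos(tilt), np.sin(tilt)
    tangent = np.array([radial[1], -radial[0]])
    direction = ct * tangent + st * radial
    p0 = start - direction * length / 2
    p2 = start + direction * length / 2
    p1 = start + radial * curv * length  # bend away from the nucleus
    t = np.linspace(0, 1, max(int(2 * length), 16))[:, None]
    curve = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    for pt in curve:
        _stamp_disc(mask, pt, thick / 2)


def generate_cell_image(config: ImageSimConfig) -> SimulatedImage:
    """Simulate one field of view with per-cell ground-truth labels.

    Exactly ``round-half-up(n_cells * frac_filamented)`` cells carry
    filament-like objects; the rest carry puncta.  Labels are returned in
    ``cell_id`` order.  With ``n_cells=0`` the field is background + noise
    only.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    px = cfg.pixel_size_um

    centres = _place_nuclei(cfg, rng)
    n_fil = _round_half_up(cfg.n_cells * cfg.frac_filamented)
    is_filamented = np.zeros(cfg.n_cells, dtype=bool)
    is_filamented[rng.permutation(cfg.n_cells)[:n_fil]] = True

    nucleus_mask = np.zeros(shape, dtype=bool)
    object_mask = np.zeros(shape, dtype=bool)
    labels: list[GroundTruthLabel] = []
    for cid in range(cfg.n_cells):
        centre = centres[cid]
        nuc_r = rng.uniform(*cfg.nucleus_radius_um) / px
        _stamp_disc(nucleus_mask, centre, nuc_r)
        cell_obj = np.zeros(shape, dtype=bool)
        if is_filamented[cid]:
            count = rng.integers(
                cfg.filaments_per_cell[0], cfg.filaments_per_cell[1] + 1
            )
            for _ in range(count):
                _stamp_filament(cell_obj, centre, nuc_r, cfg, rng)
            true_class = "filamented"
        else:
            count = rng.integers(cfg.puncta_per_cell[0], cfg.puncta_per_cell[1] + 1)
            placed = 0
            for _ in range(count):
                radius = rng.uniform(*cfg.puncta_diameter_um) / 2 / px
                lo = nuc_r + radius + 8.0
                hi = max(cfg.cell_extent_um / px - radius, lo + 0.5)
                offset = rng.uniform(lo, hi)
                phi = rng.uniform(0, 2 * np.pi)
                pos = centre + offset * np.array([np.sin(phi), np.cos(phi)])
                _stamp_disc(cell_obj, pos, radius)
                placed += 1
            true_class = "punctuated"
        # objects must not sit on the nucleus (cytoplasmic localisation)
        cell_obj &= ~nucleus_mask
        object_mask |= cell_obj
        labels.append(
            GroundTruthLabel(
                cell_id=cid,
                true_class=true_class,
                nucleus_centroid=(float(centre[0]), float(centre[1])),
                object_count=int(count),
            )
        )

    nuclear = cfg.background_level + cfg.signal_level * nucleus_mask
    reporter = (
        cfg.background_level
        + cfg.signal_level * object_mask
        + cfg.nuclear_ghost * cfg.signal_level * (nucleus_mask & ~object_mask)
    )
    if cfg.noise_sd > 0:
        nuclear = nuclear + rng.normal(0.0, cfg.noise_sd, shape)
        reporter = reporter + rng.normal(0.0, cfg.noise_sd, shape)
    return SimulatedImage(nuclear, reporter, labels, nucleus_mask, object_mask)


def generate_image_set(
    config: ImageSimConfig, n_images: int
) -> list[SimulatedImage]:
    """Independent fields with per-image RNG streams derived from
    ``(seed, image index)``, so images are reproducible in any order."""
    out = []
    for i in range(n_images):
        child = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg_i = ImageSimConfig(**{**config.__dict__, "seed": sub_seed})
        out.append(generate_cell_image(cfg_i))
    return out


# ---------------------------------------------------------------------------
# toy protomer
# ---------------------------------------------------------------------------


def make_toy_protomer(
    n_pseudo_atoms: int, spread: float = 10.0, seed: int = 0
) -> StructureModel:
    """A reproducible rigid pseudo-atom cloud for geometry round-trips.

    The cloud is centred on the origin, non-collinear, and has distinct
    pairwise distances so rigid superposition is unambiguous.
    """
    if n_pseudo_atoms < 3:
        raise ValueError("need at least 3 pseudo-atoms")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        pts = rng.uniform(-spread, spread, size=(n_pseudo_atoms, 3))
        pts -= pts.mean(axis=0)
        sv = np.linalg.svd(pts, compute_uv=False)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dists = np.sort(d[np.triu_indices(n_pseudo_atoms, 1)])
        if sv[1] > 1e-6 * spread and np.all(np.diff(dists) > 1e-9 * spread):
            return StructureModel(pts)
    raise RuntimeError("could not generate a non-degenerate point cloud")


# ---------------------------------------------------------------------------
# assay datasets
# ---------------------------------------------------------------------------

_ASSAY_MODELS = ("michaelis_menten", "hill_activation", "thermal_sigmoid",
                 "itc_two_sets")


@dataclass
class AssaySimConfig:
    """Noisy draws from a forward model at stated ground-truth parameters.

    ``true_params`` is the parameter object for the chosen model
    (:class:`~filaquant.binding.MMParams`, ``HillActivationParams``,
    ``ThermalParams`` or ``ITCTwoSetsParams``); ``design`` is the x-grid
    (or an :class:`~filaquant.binding.ITCExperiment` for ITC).
    """

    model: str
    true_params: object
    design: object
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _ASSAY_MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; supported: {_ASSAY_MODELS}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.model != "itc_two_sets":
            x = np.asarray(self.design, dtype=float)
            if x.ndim != 1 or np.any(np.diff(x) <= 0):
                raise ValueError("x-grid must be strictly increasing")


def _forward(config: AssaySimConfig) -> tuple[np.ndarray, np.ndarray]:
    p = config.true_params
    if config.model == "michaelis_menten":
        x = np.asarray(config.design, dtype=float)
        return x, binding.michaelis_menten(x, p.vmax, p.km)
    if config.model == "hill_activation":
        x = np.asarray(config.design, dtype=float)
        return x, binding.hill_activation(x, p.v_basal, p.v_max, p.k_act, p.n_hill)
    if config.model == "thermal_sigmoid":
        x = np.asarray(config.design, dtype=float)
        return x, binding.thermal_sigmoid(x, p.low, p.high, p.tm, p.slope)
    # itc_two_sets
    heats = binding.itc_model_heats(p, config.design)
    return np.arange(1, heats.size + 1, dtype=float), heats


def generate_assay_dataset(config: AssaySimConfig) -> pd.DataFrame:
    """Tidy table of ``(x, replicate, response)`` with i.i.d. Gaussian noise.

    With ``noise_sd = 0`` responses equal the forward model exactly.
    """
    rng = np.random.default_rng(config.seed)
    x, y = _forward(config)
    rows = []
    for rep in range(config.replicates):
        noisy = y + (rng.normal(0.0, config.noise_sd, y.shape)
                     if config.noise_sd > 0 else 0.0)
        rows.append(pd.DataFrame({"x": x, "replicate": rep, "response": noisy}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_image(sim: SimulatedImage, out_dir, stem: str = "field") -> dict:
    """Write channels as TIFF and labels as CSV; returns the paths."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nuclear": out / f"{stem}_nuclear.tif",
        "reporter": out / f"{stem}_reporter.tif",
        "labels": out / f"{stem}_labels.csv",
    }
    tifffile.imwrite(paths["nuclear"], sim.nuclear.astype(np.float32))
    tifffile.imwrite(paths["reporter"], sim.reporter.astype(np.float32))
    pd.DataFrame(
        [
            {
                "cell_id": l.cell_id,
                "true_class": l.true_class,
                "centroid_row": l.nucleus_centroid[0],
                "centroid_col": l.nucleus_centroid[1],
                "object_count": l.object_count,
            }
            for l in sim.labels
        ]
    ).to_csv(paths["labels"], index=False)
    return paths
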