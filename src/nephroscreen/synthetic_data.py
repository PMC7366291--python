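"""Synthetic pronephros screen with known ground truth.

Generates 96-well plates the way the real assay produces them — fluorescent
z-stacks of two nephron arms joined at a fused two-lobed glomerulus, plus
per-embryo qualitative annotations and per-treatment gross-morphology
counts — from a generative model whose parameters are known exactly, so
every downstream stage (projection, ROI detection, morphometry,
normalization, profiling) can be validated against planted truth.

Generative model
----------------
Each treatment carries a multiplicative *effect vector* over the ten
morphometric parameters (controls: identically 1.0).  Each embryo draws its
true parameter vector as

    baseline × effect × lognormal(mean 1, CV)

with the lognormal keeping parameters positive.  Bilateral parameters
(left/right angles, glomerular heights and widths, tubular diameters) share
an embryo-level log-factor plus independent side noise so the two sides are
correlated, as in a real embryo.  Qualitative categories are assigned by
thresholding the true parameters against the baseline (fold cut-offs for
minor/moderate/major), an explicit stand-in for expert annotation.  Wells
are empty ("no fluorescence") with a configurable lethality probability.

Plate layout: rows A–G hold one compound each (one embryo per well,
columns 1..embryos_per_treatment), row H holds the vehicle (DMSO) control
of that plate; one plate = one experimental day.

Randomness is split hierarchically (screen → plate → well) with
``numpy.random.SeedSequence`` so regenerating one plate never consumes
another plate's draws; identical (config, seed) gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .image_processing import ZStack
from .morphometry import PARAM_NAMES, LandmarkSet
from .plate_io import (
    AnnotationRecord,
    GrossMorphologyRecord,
    WellAddress,
)

__all__ = [
    "ScreenSimConfig",
    "ScreenDesign",
    "PlateData",
    "ScreenTables",
    "RenderBoundsError",
    "sample_embryo_params",
    "assign_categories",
    "landmarks_from_params",
    "render_embryo_stack",
    "generate_plate",
    "write_plate",
    "generate_screen",
    "simulate_measurement_table",
    "simulate_screen_tables",
    "treatment_map",
    "design_screen",
]

#: Bilateral parameter pairs sharing an embryo-level factor.
BILATERAL_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("angleL", "angleR"),
    ("glomHeightL", "glomHeightR"),
    ("glomWidthL", "glomWidthR"),
    ("tubDiamL", "tubDiamR"),
)
UNILATERAL_PARAMS: Tuple[str, ...] = ("tubDist", "glomSep")

_ANGLE_PARAMS = ("angleL", "angleR")

#: Baseline (vehicle-control) geometry in pixels/degrees, sized for the
#: dorsal 4x field of view where the pronephros fits a 257-px thumbnail.
DEFAULT_BASELINE: Dict[str, float] = {
    "angleL": 120.0,
    "angleR": 120.0,
    "tubDist": 150.0,
    "glomHeightL": 45.0,
    "glomHeightR": 45.0,
    "glomSep": 35.0,
    "glomWidthL": 40.0,
    "glomWidthR": 40.0,
    "tubDiamL": 18.0,
    "tubDiamR": 18.0,
}

#: Per-embryo rates of gross-morphology findings among exposed embryos.
#: Independent of the renal effect vectors: extrarenal toxicity is modelled
#: as a separate axis (the screen found no strong edema-renal correlation).
DEFAULT_GROSS_RATES: Dict[str, float] = {
    "curved_back_tail": 0.05,
    "edema_mild": 0.08,
    "edema_severe": 0.02,
    "heartbeat_faster": 0.02,
    "heartbeat_slower": 0.02,
    "heartbeat_absent": 0.01,
    "somite_malformation": 0.03,
    "yolk_necrosis": 0.02,
}

_COMPOUND_ROWS = "ABCDEFG"  # row H is reserved for the plate control


class RenderBoundsError(ValueError):
    """The requested geometry does not fit inside the image frame."""


class ConfigurationError(ValueError):
    """The simulation configuration is inconsistent."""


@dataclass(frozen=True)
class ScreenSimConfig:
    """Generative parameters of a synthetic screen.

    Parameters
    ----------
    effect_vectors
        One multiplicative factor per morphometric parameter for every
        compound, keyed by treatment ID, in :data:`PARAM_NAMES` order.
        Controls are added automatically (one ``DMSO_<plate>`` group per
        plate) with effect identically 1.0.
    biological_cv
        Coefficient of variation of the per-embryo lognormal factor, per
        parameter (a scalar applies to all ten).
    bilateral_correlation
        Correlation of the log-factors within a left/right pair.
    lethality_prob
        Probability that a well position is empty (dead/unloaded embryo).
    psf_sigma / defocus_sigma_per_slice
        In-focus Gaussian blur SD and its growth per slice of defocus (px).
    read_noise_sd / shot_noise
        Gaussian read noise SD (counts) and Poisson shot-noise toggle.
    """

    n_compounds: int
    effect_vectors: Mapping[str, Tuple[float, ...]]
    wells_per_plate: int = 96
    embryos_per_treatment: int = 8
    control_row: str = "H"
    baseline_geometry: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    biological_cv: float | Mapping[str, float] = 0.1
    bilateral_correlation: float = 0.5
    pancreas_tox: Mapping[str, float] = field(default_factory=dict)
    lethality_prob: float = 0.1
    read_noise_sd: float = 5.0
    shot_noise: bool = True
    psf_sigma: float = 1.0
    defocus_sigma_per_slice: float = 2.0
    n_slices: int = 10
    slice_spacing_um: float = 15.0
    image_size: Tuple[int, int] = (2048, 2048)
    background: float = 100.0
    amplitude: float = 10000.0
    center_jitter: float = 0.08
    gross_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROSS_RATES)
    )
    total_exposed: int = 20
    cat_minor: float = 1.2
    cat_moderate: float = 1.35
    cat_major: float = 1.5
    cat_malform: float = 1.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ConfigurationError("need at least one compound")
        if not 1 <= self.embryos_per_treatment <= 12:
            raise ConfigurationError("embryos_per_treatment must be in 1..12")
        if self.control_row not in "ABCDEFGH":
            raise ConfigurationError("control_row must be a letter A-H")
        if self.control_row in _COMPOUND_ROWS:
            raise ConfigurationError(
                f"control row {self.control_row!r} collides with compound rows"
            )
        if set(self.baseline_geometry) != set(PARAM_NAMES):
            raise ConfigurationError(
                "baseline_geometry must name exactly the 10 morphometric parameters"
            )
        for name, v in self.baseline_geometry.items():
            if not (v > 0 and math.isfinite(v)):
                raise ConfigurationError(f"baseline {name}={v!r} must be finite > 0")
        for name, cv in self.cv_by_param().items():
            if not (cv >= 0 and math.isfinite(cv)):
                raise ConfigurationError(f"CV for {name} must be finite >= 0")
        if not 0.0 <= self.bilateral_correlation <= 1.0:
            raise ConfigurationError("bilateral_correlation must be in [0, 1]")
        for prob_name in ("lethality_prob",):
            p = getattr(self, prob_name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{prob_name} must be a probability")
        for name, p in self.gross_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"gross rate {name} must be a probability")
        for name in ("read_noise_sd", "psf_sigma", "defocus_sigma_per_slice",
                     "slice_spacing_um", "background", "amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")
        if len(self.effect_vectors) != self.n_compounds:
            raise ConfigurationError(
                f"effect_vectors has {len(self.effect_vectors)} entries "
                f"for {self.n_compounds} compounds"
            )
        for tid, vec in self.effect_vectors.items():
            if len(vec) != len(PARAM_NAMES):
                raise ConfigurationError(
                    f"effect vector for {tid!r} has length {len(vec)}, expected 10"
                )
            if any(not (f > 0 and math.isfinite(f)) for f in vec):
                raise ConfigurationError(f"effect factors for {tid!r} must be > 0")
        if not 1.0 <= self.cat_minor <= self.cat_moderate <= self.cat_major:
            raise ConfigurationError("category thresholds must be ordered >= 1")

    # -- derived layout ----------------------------------------------------

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_compounds / len(_COMPOUND_ROWS))

    def compound_ids(self) -> List[str]:
        return sorted(self.effect_vectors)

    def plate_id(self, plate_index: int) -> str:
        return f"P{plate_index + 1:02d}"

    def day_id(self, plate_index: int) -> str:
        return f"day{plate_index + 1:02d}"

    def control_treatment(self, plate_index: int) -> str:
        return f"DMSO_{self.plate_id(plate_index)}"

    def plate_layout(self, plate_index: int) -> Dict[str, str]:
        """Row letter → treatment ID for one plate."""
        ids = self.compound_ids()
        start = plate_index * len(_COMPOUND_ROWS)
        if not 0 <= plate_index < self.n_plates:
            raise ConfigurationError(f"plate index {plate_index} out of range")
        layout = {
            row: ids[start + i]
            for i, row in enumerate(_COMPOUND_ROWS)
            if start + i < len(ids)
        }
        layout[self.control_row] = self.control_treatment(plate_index)
        return layout

    def effect_for(self, treatment: str) -> np.ndarray:
        """Effect vector of a treatment; controls are identically 1."""
        if treatment.startswith("DMSO_"):
            return np.ones(len(PARAM_NAMES))
        try:
            return np.asarray(self.effect_vectors[treatment], dtype=float)
        except KeyError:
            raise ConfigurationError(f"unknown treatment ID {treatment!r}") from None

    def cv_by_param(self) -> Dict[str, float]:
        if isinstance(self.biological_cv, Mapping):
            missing = set(PARAM_NAMES) - set(self.biological_cv)
            if missing:
                raise ConfigurationError(f"biological_cv lacks {sorted(missing)}")
            return {n: float(self.biological_cv[n]) for n in PARAM_NAMES}
        return {n: float(self.biological_cv) for n in PARAM_NAMES}

    # -- (de)serialization --------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["effect_vectors"] = {k: [float(x) for x in v]
                                 for k, v in self.effect_vectors.items()}
        doc["baseline_geometry"] = {k: float(v)
                                    for k, v in self.baseline_geometry.items()}
        doc["image_size"] = list(self.image_size)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ScreenSimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["effect_vectors"] = {k: tuple(v) for k, v in doc["effect_vectors"].items()}
        doc["image_size"] = tuple(doc["image_size"])
        if isinstance(doc.get("biological_cv"), dict):
            doc["biological_cv"] = {k: float(v) for k, v in doc["biological_cv"].items()}
        return cls(**doc)


# ---------------------------------------------------------------------------
# Embryo-level sampling
# ---------------------------------------------------------------------------


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def sample_embryo_params(
    config: ScreenSimConfig, treatment: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw one embryo's true parameter vector (10 values).

    Returns ``baseline × effect × lognormal(mean 1, CV)`` per parameter,
    with bilateral pairs sharing an embryo-level log-factor (correlation
    ``bilateral_correlation``).  Deterministic given the generator state.
    Angles are capped at 180°.
    """
    effect = config.effect_for(treatment)
    cvs = config.cv_by_param()
    rho = config.bilateral_correlation
    log_factor: Dict[str, float] = {}
    for left, right in BILATERAL_PAIRS:
        z_shared = rng.standard_normal()
        for name in (left, right):
            z_side = rng.standard_normal()
            sigma = _lognormal_sigma(cvs[name])
            z = math.sqrt(rho) * z_shared + math.sqrt(1.0 - rho) * z_side
            log_factor[name] = sigma * z - 0.5 * sigma * sigma
    for name in UNILATERAL_PARAMS:
        sigma = _lognormal_sigma(cvs[name])
        log_factor[name] = sigma * rng.standard_normal() - 0.5 * sigma * sigma
    values = np.empty(len(PARAM_NAMES))
    for i, name in enumerate(PARAM_NAMES):
        v = config.baseline_geometry[name] * effect[i] * math.exp(log_factor[name])
        if name in _ANGLE_PARAMS:
            v = min(v, 180.0)
        values[i] = v
    return values


def assign_categories(config: ScreenSimConfig, params: np.ndarray) -> FrozenSet[str]:
    """Qualitative categories implied by an embryo's true parameters.

    Fold-change thresholds against the baseline stand in for the expert
    annotator: glomerular-separation and reduced-pronephric-angle tags at
    minor/moderate/major cut-offs (most severe tag only), ``glom_malform``
    when any glomerular width/height deviates by the malformation fold in
    either direction, and ``normal_kidney`` when nothing fires.  The
    pancreas tag is drawn separately per treatment during plate simulation.
    """
    p = {name: params[i] for i, name in enumerate(PARAM_NAMES)}
    base = config.baseline_geometry
    cats = set()

    sep_fold = p["glomSep"] / base["glomSep"]
    if sep_fold >= config.cat_major:
        cats.add("glomsep_maj")
    elif sep_fold >= config.cat_moderate:
        cats.add("glomsep_mod")
    elif sep_fold >= config.cat_minor:
        cats.add("glomsep_min")

    angle_fold = min(p["angleL"] / base["angleL"], p["angleR"] / base["angleR"])
    if angle_fold <= 1.0 / config.cat_major:
        cats.add("rpa_maj")
    elif angle_fold <= 1.0 / config.cat_moderate:
        cats.add("rpa_mod")
    elif angle_fold <= 1.0 / config.cat_minor:
        cats.add("rpa_min")

    for name in ("glomWidthL", "glomWidthR", "glomHeightL", "glomHeightR"):
        fold = p[name] / base[name]
        if fold >= config.cat_malform or fold <= 1.0 / config.cat_malform:
            cats.add("glom_malform")
            break

    if not cats:
        cats.add("normal_kidney")
    return frozenset(cats)


# ---------------------------------------------------------------------------
# Landmark construction and rendering
# ---------------------------------------------------------------------------

_GLOM_ROW_OFFSET = 40.0  # glomerular equator anterior of the kidney centre
_TUB_ROW_OFFSET = 30.0  # tubule measurement row posterior of the centre
_VERTEX_DROP = 45.0  # vertex posterior of the tubule measurement row
_NECK_RAY_LEN = 30.0  # distance of the neck-ray point from the vertex
_TUB_ARM_RISE = 25.0  # tubule arm extends this far anterior of the row


def landmarks_from_params(
    params: np.ndarray, center: Tuple[float, float]
) -> LandmarkSet:
    """Closed-form 16-point landmark construction for a parameter vector.

    The construction is exactly inverted by
    :func:`nephroscreen.morphometry.compute_features`: glomerular poles are
    placed at the configured separations/widths/heights around the
    glomerular equator, tubule edge points at the configured distance and
    diameters, and the neck-ray point at the configured angle from the
    vertical proximal tubule direction.
    """
    p = {name: float(params[i]) for i, name in enumerate(PARAM_NAMES)}
    cx, cy = center
    y_g = cy - _GLOM_ROW_OFFSET
    y_t = cy + _TUB_ROW_OFFSET
    pts: Dict[str, Tuple[float, float]] = {}
    for side, sgn in (("L", -1.0), ("R", 1.0)):
        width = p[f"glomWidth{side}"]
        height = p[f"glomHeight{side}"]
        x_med = cx + sgn * p["glomSep"] / 2.0
        x_lat = cx + sgn * (p["glomSep"] / 2.0 + width)
        x_mid = cx + sgn * (p["glomSep"] / 2.0 + width / 2.0)
        pts[f"{side}_glom_medial"] = (x_med, y_g)
        pts[f"{side}_glom_lateral"] = (x_lat, y_g)
        pts[f"{side}_glom_anterior"] = (x_mid, y_g - height / 2.0)
        pts[f"{side}_glom_posterior"] = (x_mid, y_g + height / 2.0)

        diam = p[f"tubDiam{side}"]
        x_tl = cx + sgn * p["tubDist"] / 2.0
        x_tr = cx + sgn * (p["tubDist"] / 2.0 - diam)
        pts[f"{side}_tubule_lateral"] = (x_tl, y_t)
        pts[f"{side}_tubule_ray"] = (x_tr, y_t)

        vx, vy = x_tr, y_t + _VERTEX_DROP
        pts[f"{side}_vertex"] = (vx, vy)
        theta = math.radians(p[f"angle{side}"])
        # the proximal tubule runs anterior (0, -1) from the vertex; the neck
        # segment opens toward the midline by the pronephric angle
        pts[f"{side}_neck_ray"] = (
            vx - sgn * _NECK_RAY_LEN * math.sin(theta),
            vy - _NECK_RAY_LEN * math.cos(theta),
        )
    return LandmarkSet(pts)


def _foreground_mask(
    params: np.ndarray, landmarks: LandmarkSet, shape: Tuple[int, int]
) -> np.ndarray:
    """Rasterize the kidney: two glomerular ellipses and two tubule arms."""
    p = {name: float(params[i]) for i, name in enumerate(PARAM_NAMES)}
    mask = np.zeros(shape, dtype=bool)
    pad = 0.8  # rasterization margin so boundary landmarks fall on foreground
    for side in ("L", "R"):
        ax, ay = landmarks[f"{side}_glom_anterior"]
        px_, py = landmarks[f"{side}_glom_posterior"]
        ccx = (landmarks[f"{side}_glom_medial"][0]
               + landmarks[f"{side}_glom_lateral"][0]) / 2.0
        ccy = (ay + py) / 2.0
        rr, cc = draw_ellipse(
            ccy,
            ccx,
            p[f"glomHeight{side}"] / 2.0 + pad,
            p[f"glomWidth{side}"] / 2.0 + pad,
            shape=shape,
        )
        mask[rr, cc] = True

        # proximal tubule arm: axis-aligned band from the measurement row up
        # toward the glomerulus and down to the vertex
        x_lat, y_t = landmarks[f"{side}_tubule_lateral"]
        x_med, _ = landmarks[f"{side}_tubule_ray"]
        vx, vy = landmarks[f"{side}_vertex"]
        x0 = min(x_lat, x_med) - pad
        x1 = max(x_lat, x_med) + pad
        y0 = y_t - _TUB_ARM_RISE
        y1 = vy + pad
        rr, cc = draw_polygon(
            [y0, y0, y1, y1], [x0, x1, x1, x0], shape=shape
        )
        mask[rr, cc] = True

        # neck segment: capsule of tubular diameter from vertex to neck ray
        nx, ny = landmarks[f"{side}_neck_ray"]
        half = p[f"tubDiam{side}"] / 2.0 + pad
        dx, dy = nx - vx, ny - vy
        norm = math.hypot(dx, dy)
        ox, oy = -dy / norm * half, dx / norm * half
        rr, cc = draw_polygon(
            [vy + oy, ny + oy, ny - oy, vy - oy],
            [vx + ox, nx + ox, nx - ox, vx - ox],
            shape=shape,
        )
        mask[rr, cc] = True
        for ex, ey in ((vx, vy), (nx, ny)):
            rr, cc = draw_disk((ey, ex), half, shape=shape)
            mask[rr, cc] = True
    return mask


def render_embryo_stack(
    params: np.ndarray,
    config: ScreenSimConfig,
    rng: np.random.Generator,
    center: Optional[Tuple[float, float]] = None,
) -> Tuple[ZStack, LandmarkSet]:
    """Render one embryo's fluorescence z-stack and its ground-truth landmarks.

    The structure is in focus at the central slice; away from it every slice
    is blurred by a Gaussian whose SD grows with the defocus distance, then
    Poisson shot noise and Gaussian read noise are applied per the config.
    The kidney centre is jittered around the frame centre unless ``center``
    is given.  Raises :class:`RenderBoundsError` if the geometry (plus a
    2-px margin) would leave the frame.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (len(PARAM_NAMES),) or not (params > 0).all():
        raise ValueError("params must be 10 positive values")
    h, w = int(config.image_size[0]), int(config.image_size[1])
    if center is None:
        jx = rng.uniform(-config.center_jitter, config.center_jitter) * w
        jy = rng.uniform(-config.center_jitter, config.center_jitter) * h
        center = (w / 2.0 + jx, h / 2.0 + jy)
    landmarks = landmarks_from_params(params, center)
    coords = landmarks.as_array()
    margin = 2.0
    if (
        coords[:, 0].min() < margin
        or coords[:, 1].min() < margin
        or coords[:, 0].max() > w - 1 - margin
        or coords[:, 1].max() > h - 1 - margin
    ):
        raise RenderBoundsError(
            f"kidney geometry exceeds the {w}x{h} frame at centre {center}"
        )

    mask = _foreground_mask(params, landmarks, (h, w))
    sharp = np.full((h, w), config.background, dtype=float)
    sharp[mask] += config.amplitude

    focal = config.n_slices // 2
    slices = np.empty((config.n_slices, h, w), dtype=np.uint16)
    for k in range(config.n_slices):
        sigma = config.psf_sigma + config.defocus_sigma_per_slice * abs(k - focal)
        img = gaussian_filter(sharp, sigma) if sigma > 0 else sharp.copy()
        if config.shot_noise:
            img = rng.poisson(img).astype(float)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
        slices[k] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    stack = ZStack(
        pixels=slices, channel="GFP", slice_spacing_um=config.slice_spacing_um
    )
    return stack, landmarks


# ---------------------------------------------------------------------------
# Plate and screen generation
# ---------------------------------------------------------------------------


@dataclass
class PlateData:
    """One generated plate: stacks plus ground truth and score tables."""

    plate_id: str
    day: str
    stacks: Dict[str, ZStack]  # well label -> stack (non-empty wells only)
    landmarks: Dict[Tuple[str, str, int], LandmarkSet]
    ground_truth: pd.DataFrame  # one row per well
    annotations: List[AnnotationRecord]
    gross: List[GrossMorphologyRecord]


@dataclass
class ScreenTables:
    """Image-free simulation output feeding the scoring module directly."""

    features: pd.DataFrame  # per-embryo true parameters, plate_io schema
    annotations: List[AnnotationRecord]
    gross: List[GrossMorphologyRecord]
    ground_truth: pd.DataFrame  # one row per treatment: planted effects


def _well_rng(config: ScreenSimConfig, plate_index: int, well_index: int):
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(plate_index, well_index)
    )
    return np.random.default_rng(ss)


def _plate_rng(config: ScreenSimConfig, plate_index: int):
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(plate_index, 10_000))
    return np.random.default_rng(ss)


def _iter_wells(
    config: ScreenSimConfig, plate_index: int
) -> Iterator[Tuple[WellAddress, str, int]]:
    """Yield (well, treatment, well_index) for every occupied position."""
    plate = config.plate_id(plate_index)
    layout = config.plate_layout(plate_index)
    for r, row in enumerate("ABCDEFGH"):
        if row not in layout:
            continue
        for col in range(1, config.embryos_per_treatment + 1):
            yield (
                WellAddress(plate=plate, row=row, column=col),
                layout[row],
                r * 12 + (col - 1),
            )


def _simulate_plate_wells(config: ScreenSimConfig, plate_index: int):
    """Common per-well draws for both the image and the fast path.

    For each occupied well: lethality draw, then (if alive) parameter draw,
    pancreas draw and category assignment — all from the well's own stream
    so the two paths produce identical values.
    """
    out = []
    for well, treatment, well_index in _iter_wells(config, plate_index):
        rng = _well_rng(config, plate_index, well_index)
        dead = bool(rng.random() < config.lethality_prob)
        if dead:
            out.append((well, treatment, None, frozenset({"empty"}), rng))
            continue
        params = sample_embryo_params(config, treatment, rng)
        cats = set(assign_categories(config, params))
        panc_prob = float(config.pancreas_tox.get(treatment, 0.0))
        if rng.random() < panc_prob:
            cats.add("liver-panc_pheno")
            cats.discard("normal_kidney")
        out.append((well, treatment, params, frozenset(cats), rng))
    return out


def _simulate_gross(
    config: ScreenSimConfig, plate_index: int
) -> List[GrossMorphologyRecord]:
    rng = _plate_rng(config, plate_index)
    layout = config.plate_layout(plate_index)
    records = []
    n = config.total_exposed
    for row in sorted(layout):
        treatment = layout[row]
        counts = {
            name: int(rng.binomial(n, rate))
            for name, rate in sorted(config.gross_rates.items())
        }
        mortality = int(rng.binomial(n, config.lethality_prob))
        records.append(
            GrossMorphologyRecord(
                treatment=treatment,
                mortality=mortality,
                total_exposed=n,
                **counts,
            )
        )
    return records


def generate_plate(
    config: ScreenSimConfig, plate_index: int, render_images: bool = True
) -> PlateData:
    """Generate one plate: stacks, ground truth, annotations, gross counts.

    Empty wells (lethality draw) get no stack and the single category
    ``"empty"``.  Fully reproducible from (config.seed, plate_index).
    """
    plate = config.plate_id(plate_index)
    day = config.day_id(plate_index)
    stacks: Dict[str, ZStack] = {}
    landmark_sets: Dict[Tuple[str, str, int], LandmarkSet] = {}
    truth_rows = []
    annotations = []
    for well, treatment, params, cats, rng in _simulate_plate_wells(
        config, plate_index
    ):
        annotations.append(
            AnnotationRecord(well=well, embryo=1, categories=cats)
        )
        row = {
            "plate": plate,
            "well": well.label,
            "day": day,
            "treatment": treatment,
            "is_control": treatment.startswith("DMSO_"),
            "empty": params is None,
            "categories": ";".join(sorted(cats)),
        }
        if params is not None:
            row.update({name: params[i] for i, name in enumerate(PARAM_NAMES)})
            if render_images:
                stack, lms = render_embryo_stack(params, config, rng)
                stacks[well.label] = stack
                landmark_sets[(plate, well.label, 1)] = lms
        truth_rows.append(row)
    columns = [
        "plate", "well", "day", "treatment", "is_control", "empty",
        "categories", *PARAM_NAMES,
    ]
    ground_truth = pd.DataFrame(truth_rows).reindex(columns=columns)
    return PlateData(
        plate_id=plate,
        day=day,
        stacks=stacks,
        landmarks=landmark_sets,
        ground_truth=ground_truth,
        annotations=annotations,
        gross=_simulate_gross(config, plate_index),
    )


def write_plate(plate: PlateData, screen_dir) -> None:
    """Write a plate in the layout plate_io reads.

    TIFF stacks under ``{screen}/{plate}/{well}_GFP.tif`` plus per-plate
    CSVs for annotations, gross counts, ground-truth landmarks and true
    parameters.
    """
    from . import plate_io
    from .morphometry import write_landmarks

    screen_dir = Path(screen_dir)
    plate_dir = screen_dir / plate.plate_id
    plate_dir.mkdir(parents=True, exist_ok=True)
    for well_label, stack in plate.stacks.items():
        address = WellAddress.parse(plate.plate_id, well_label)
        plate_io.write_stack(stack, plate_io.stack_path(screen_dir, address))
    plate_io.write_annotations(
        plate.annotations, plate_dir / "annotations.csv"
    )
    plate_io.write_gross_morphology(plate.gross, plate_dir / "gross.csv")
    write_landmarks(plate.landmarks, plate_dir / "landmarks.csv")
    plate.ground_truth.to_csv(plate_dir / "ground_truth.csv", index=False)


def generate_screen(
    config: ScreenSimConfig, screen_dir, render_images: bool = True
) -> List[PlateData]:
    """Generate and write every plate of the screen; returns the plate data."""
    plates = []
    for p in range(config.n_plates):
        plate = generate_plate(config, p, render_images=render_images)
        write_plate(plate, screen_dir)
        plates.append(plate)
    return plates


def _treatment_truth(config: ScreenSimConfig) -> pd.DataFrame:
    rows = []
    for p in range(config.n_plates):
        layout = config.plate_layout(p)
        for row_letter in sorted(layout):
            tid = layout[row_letter]
            effect = config.effect_for(tid)
            rows.append(
                {
                    "treatment": tid,
                    "day": config.day_id(p),
                    "plate": config.plate_id(p),
                    "is_control": tid.startswith("DMSO_"),
                    "planted_abnormal": bool(np.any(effect != 1.0)),
                    **{f"effect_{n}": effect[i] for i, n in enumerate(PARAM_NAMES)},
                }
            )
    return pd.DataFrame(rows).drop_duplicates("treatment").reset_index(drop=True)


def simulate_screen_tables(config: ScreenSimConfig) -> ScreenTables:
    """Simulate the whole screen without rendering any images.

    Emits the same per-embryo feature schema that measuring the rendered
    plates would produce (the true parameters, since landmark round-trips
    are exact by construction), plus annotations, gross counts and the
    per-treatment planted truth.
    """
    feature_rows = []
    annotations: List[AnnotationRecord] = []
    gross: List[GrossMorphologyRecord] = []
    for p in range(config.n_plates):
        plate = config.plate_id(p)
        day = config.day_id(p)
        for well, treatment, params, cats, _rng in _simulate_plate_wells(config, p):
            annotations.append(AnnotationRecord(well=well, embryo=1, categories=cats))
            if params is not None:
                feature_rows.append(
                    {
                        "plate": plate,
                        "well": well.label,
                        "day": day,
                        "treatment": treatment,
                        "embryo": 1,
                        "is_control": treatment.startswith("DMSO_"),
                        **{n: params[i] for i, n in enumerate(PARAM_NAMES)},
                    }
                )
        gross.extend(_simulate_gross(config, p))
    features = pd.DataFrame(
        feature_rows,
        columns=[
            "plate", "well", "day", "treatment", "embryo", "is_control",
            *PARAM_NAMES,
        ],
    )
    return ScreenTables(
        features=features,
        annotations=annotations,
        gross=gross,
        ground_truth=_treatment_truth(config),
    )


def simulate_measurement_table(config: ScreenSimConfig) -> pd.DataFrame:
    """Image-free fast path: the per-embryo feature table only."""
    return simulate_screen_tables(config).features


def treatment_map(config: ScreenSimConfig) -> Dict[Tuple[str, str], str]:
    """(plate, well label) → treatment ID for every occupied well position."""
    return {
        (well.plate, well.label): treatment
        for p in range(config.n_plates)
        for well, treatment, _ in _iter_wells(config, p)
    }


# ---------------------------------------------------------------------------
# Screen design: effect vectors, compound library, synthetic ATC classes
# ---------------------------------------------------------------------------


@dataclass
class ScreenDesign:
    """A designed synthetic screen: config inputs plus planted truth."""

    effect_vectors: Dict[str, Tuple[float, ...]]
    compounds: pd.DataFrame  # compound_id, name, library_position
    atc: pd.DataFrame  # compound_id, atc_code
    strong_compounds: FrozenSet[str]
    bad_classes: FrozenSet[str]  # D-level codes planted as hit classes


def _synthetic_atc_code(index: int) -> str:
    letters = "ABCDGHJLMNPRSV"
    first = letters[index % len(letters)]
    num = (index // len(letters)) % 99 + 1
    sub = "AB"[(index // (len(letters) * 99)) % 2]
    return f"{first}{num:02d}A{sub}"


def design_screen(
    n_compounds: int = 200,
    seed: int = 0,
    class_size: int = 8,
    n_bad_classes: int = 3,
    bad_class_strong_fraction: float = 0.75,
    n_extra_strong: int = 2,
    na_fraction: float = 0.15,
    strong_fold: float = 1.5,
) -> ScreenDesign:
    """Plant effect vectors and a synthetic compound library with ATC classes.

    "Strong" compounds shift all ten morphometric parameters: angles are
    reduced by ``strong_fold`` and each length parameter is moved up or down
    by ``strong_fold`` (direction drawn per compound/parameter) — a gross
    morphological malformation, the kind of multi-feature fingerprint
    treated compound classes show.  ``n_bad_classes`` ATC D-level classes
    receive strong effects in ``bad_class_strong_fraction`` of their
    members; a few extra strong singletons sit in other classes.  A fraction
    of compounds has no ATC mapping (D-level ``N/A``), mirroring library
    reality.
    """
    if not 0 < bad_class_strong_fraction <= 1:
        raise ConfigurationError("bad_class_strong_fraction must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(77,)))
    ids = [f"C{i + 1:04d}" for i in range(n_compounds)]
    n_na = int(round(na_fraction * n_compounds))
    shuffled = list(ids)
    rng.shuffle(shuffled)
    na_ids = set(shuffled[:n_na])
    assigned = [c for c in shuffled[n_na:]]
    n_classes = max(1, math.ceil(len(assigned) / class_size))
    class_codes = [_synthetic_atc_code(i) for i in range(n_classes)]
    class_of: Dict[str, str] = {}
    members: Dict[str, List[str]] = {code: [] for code in class_codes}
    for i, cid in enumerate(assigned):
        code = class_codes[i % n_classes]
        class_of[cid] = code
        members[code].append(cid)

    eligible = [c for c in class_codes if len(members[c]) >= 4]
    # small screens may not support the requested number of planted classes
    bad = list(rng.choice(eligible, size=min(n_bad_classes, len(eligible)),
                          replace=False))
    strong: set = set()
    for code in bad:
        mem = members[code]
        k = max(
            math.ceil(0.5 * len(mem)),
            int(round(bad_class_strong_fraction * len(mem))),
        )
        strong.update(rng.choice(mem, size=min(k, len(mem)), replace=False))
    # extra strong singletons outside the planted classes (at most one per
    # class so no extra class crosses the >= 50% abnormal cut-off)
    other_classes = [c for c in class_codes if c not in bad and len(members[c]) >= 4]
    for code in rng.choice(
        other_classes, size=min(n_extra_strong, len(other_classes)), replace=False
    ):
        strong.add(str(rng.choice(members[code])))

    effect_vectors: Dict[str, Tuple[float, ...]] = {}
    for cid in ids:
        if cid in strong:
            vec = []
            for name in PARAM_NAMES:
                if name in _ANGLE_PARAMS:
                    vec.append(1.0 / strong_fold)
                else:
                    up = bool(rng.random() < 0.5)
                    vec.append(strong_fold if up else 1.0 / strong_fold)
            effect_vectors[cid] = tuple(vec)
        else:
            effect_vectors[cid] = tuple([1.0] * len(PARAM_NAMES))

    compounds = pd.DataFrame(
        {
            "compound_id": ids,
            "name": [f"Compound {i + 1:04d}" for i in range(n_compounds)],
            "library_position": [
                f"LP{i // 96 + 1:02d}-{'ABCDEFGH'[(i % 96) // 12]}{i % 12 + 1:02d}"
                for i in range(n_compounds)
            ],
        }
    )
    atc_rows = [
        {"compound_id": cid, "atc_code": f"{class_of[cid]}{1:02d}"}
        for cid in ids
        if cid not in na_ids
    ]
    atc = pd.DataFrame(atc_rows, columns=["compound_id", "atc_code"])
    return ScreenDesign(
        effect_vectors=effect_vectors,
        compounds=compounds,
        atc=atc,
        strong_compounds=frozenset(str(s) for s in strong),
        bad_classes=frozenset(str(b) for b in bad),
    )
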