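"""Seeded synthetic-data generators with ground truth for every pipeline stage.

The generators emulate the data a 384-well high-content steatosis screen
produces: two-channel field images (a nuclear stain and a neutral-lipid stain
in which lipid droplets appear as small bright cytoplasmic spots), whole
plates with stimulator (maximal lipid) and neutral (no induction) control
columns, dose-response series with multiplicative noise, qPCR Cq tables, and
compound libraries with clustered fingerprints and compound-target potency
annotations.

Every generator is a pure function of its parameters and a seed: identical
inputs give bit-identical outputs. Ground truth (nucleus/droplet geometry,
per-well effects, planted fold changes, family labels) is returned alongside
the data so downstream recovery can be scored exactly.

Rendering choices: nuclei are Gaussian-tapered disks (a flat core with a
smooth skirt), which exercises thresholding and shape filters; droplets are
uniform-intensity hard disks, so a droplet of intensity I over A pixels
contributes exactly A*I of signal above background and noiseless recovery is
well defined. Droplet inclusion uses uniform-threshold coupling (candidate i
is included iff u_i < steatosis level), which makes the expected droplet
count exactly ``level * max_droplets`` and the ground-truth signal monotone
in the level for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import four_pl

__all__ = [
    "PackingError",
    "Nucleus",
    "Droplet",
    "FieldTruth",
    "FieldImage",
    "FieldParams",
    "generate_field",
    "PlateSpec",
    "PlateGenParams",
    "generate_plate",
    "generate_well_images",
    "DoseSeriesSpec",
    "generate_dose_series",
    "six_point_range",
    "ten_point_range",
    "CqSpec",
    "generate_cq_table",
    "generate_compound_set",
    "well_id",
    "WELL_SUMMARY_COLUMNS",
]


class PackingError(ValueError):
    """Raised when requested nuclei cannot be placed at the density limit."""


def well_id(row: int, col: int) -> str:
    """0-based (row, col) -> plate well id 'A01'..'P24'."""
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def disk_area(radius: float) -> int:
    """Pixel count of the discrete disk {(dx,dy): dx^2+dy^2 <= r^2}."""
    r = int(math.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return int(np.count_nonzero(x * x + y * y <= radius * radius))


# ---------------------------------------------------------------------------
# Field images


@dataclass
class Nucleus:
    center: tuple[float, float]  # (row, col) px
    radius: float
    peak: float  # intensity above background, AU
    valid: bool = True


@dataclass
class Droplet:
    center: tuple[float, float]
    radius: float
    intensity: float  # uniform intensity above background, AU
    owner: int  # index into FieldTruth.nuclei
    area_px: int = 0  # rendered pixel count

    @property
    def integrated(self) -> float:
        return self.area_px * self.intensity


@dataclass
class FieldTruth:
    """Ground truth for one generated field."""

    nuclei: list[Nucleus]
    droplets: list[Droplet]
    background: tuple[float, float]  # (nuclear, lipid) AU
    noise_sigma: tuple[float, float]
    shape: tuple[int, int]

    def per_cell_signal(self) -> dict[int, float]:
        out = {i: 0.0 for i, n in enumerate(self.nuclei) if n.valid}
        for d in self.droplets:
            out[d.owner] = out.get(d.owner, 0.0) + d.integrated
        return out

    def per_cell_count(self) -> dict[int, int]:
        out = {i: 0 for i, n in enumerate(self.nuclei) if n.valid}
        for d in self.droplets:
            out[d.owner] = out.get(d.owner, 0) + 1
        return out

    def total_signal(self) -> float:
        return float(sum(d.integrated for d in self.droplets))


@dataclass
class FieldImage:
    """One imaged field: nuclear-channel and lipid-channel rasters (AU)."""

    nuclear: np.ndarray
    lipid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear.shape


@dataclass
class FieldParams:
    """Generative conditions for one field.

    Defaults emulate a 20x field of hepatocyte-like cells: ~200 nuclei of
    8-12 px radius in a 1080x1080 px field, droplets of radius 2 px placed in
    a 15 px annulus around their owner nucleus, and additive Gaussian camera
    noise (optionally with Poisson shot noise). ``steatosis_level`` in [0, 1]
    scales the droplet load from none (neutral control) to maximal
    (stimulator control).
    """

    shape: tuple[int, int] = (1080, 1080)
    n_nuclei: int = 200
    n_invalid: int = 0  # extra fragmented (under-sized) nuclei, flagged invalid
    nucleus_radius: tuple[float, float] = (8.0, 12.0)
    nucleus_peak: tuple[float, float] = (500.0, 700.0)
    taper_px: float = 1.5
    invalid_radius: float = 3.0
    background: tuple[float, float] = (100.0, 50.0)
    noise_sigma: tuple[float, float] = (0.0, 0.0)
    poisson_noise: bool = False
    steatosis_level: float = 1.0
    max_droplets_per_cell: int = 12
    droplet_radius: float = 2.0
    droplet_intensity: tuple[float, float] = (250.0, 350.0)
    droplet_clearance_px: float = 4.0  # annulus inner margin beyond the nucleus edge
    ring_width: int = 15
    min_separation: float | None = None  # default: 2*max radius + 8
    max_packing_fraction: float = 0.25
    max_place_attempts: int = 500


def _render_nucleus(img: np.ndarray, nuc: Nucleus, taper: float) -> None:
    r0, c0 = nuc.center
    reach = int(math.ceil(nuc.radius + 4 * taper))
    rlo, rhi = max(0, int(r0) - reach), min(img.shape[0], int(r0) + reach + 1)
    clo, chi = max(0, int(c0) - reach), min(img.shape[1], int(c0) + reach + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    d = np.hypot(rr - r0, cc - c0)
    prof = np.where(
        d <= nuc.radius,
        nuc.peak,
        nuc.peak * np.exp(-0.5 * ((d - nuc.radius) / taper) ** 2),
    )
    img[rlo:rhi, clo:chi] += prof


def _render_droplet(img: np.ndarray, d: Droplet) -> int:
    r0, c0 = d.center
    reach = int(math.ceil(d.radius))
    rlo, rhi = max(0, int(r0) - reach), min(img.shape[0], int(r0) + reach + 1)
    clo, chi = max(0, int(c0) - reach), min(img.shape[1], int(c0) + reach + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= d.radius ** 2
    img[rlo:rhi, clo:chi][mask] += d.intensity
    return int(mask.sum())


def _place_nuclei(params: FieldParams, rng: np.random.Generator) -> list[Nucleus]:
    h, w = params.shape
    r_lo, r_hi = params.nucleus_radius
    min_sep = params.min_separation or (2 * r_hi + 8.0)
    n_total = params.n_nuclei + params.n_invalid
    # coarse packing limit before attempting placement
    demand = n_total * math.pi * (min_sep / 2.0) ** 2
    if demand > params.max_packing_fraction * 4 * h * w:
        raise PackingError(
            f"cannot place {n_total} nuclei with separation {min_sep:.1f}px in a "
            f"{h}x{w} field: exceeds packing fraction limit {params.max_packing_fraction}"
        )
    margin = r_hi + params.ring_width + params.droplet_radius + 1
    if 2 * margin >= min(h, w):
        raise PackingError(f"field {h}x{w} too small for margin {margin:.0f}px")
    nuclei: list[Nucleus] = []
    centers: list[tuple[float, float]] = []
    for i in range(n_total):
        invalid = i >= params.n_nuclei
        radius = params.invalid_radius if invalid else rng.uniform(r_lo, r_hi)
        peak = rng.uniform(*params.nucleus_peak)
        for _ in range(params.max_place_attempts):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            if all(math.hypot(r0 - a, c0 - b) >= min_sep for a, b in centers):
                centers.append((r0, c0))
                nuclei.append(Nucleus((r0, c0), radius, peak, valid=not invalid))
                break
        else:
            raise PackingError(
                f"failed to place nucleus {i} after {params.max_place_attempts} "
                f"attempts at separation {min_sep:.1f}px (packing limit)"
            )
    return nuclei


def _place_droplets(
    params: FieldParams, nuclei: list[Nucleus], rng: np.random.Generator
) -> list[Droplet]:
    level = params.steatosis_level
    if not 0.0 <= level <= 1.0:
        raise ValueError("steatosis_level must lie in [0, 1]")
    dr = params.droplet_radius
    min_drop_sep = 2 * dr + 3.0  # keeps any two droplets separable by >2px centers
    droplets: list[Droplet] = []
    placed: list[tuple[float, float]] = []  # all candidate positions, field-wide
    for idx, nuc in enumerate(nuclei):
        if not nuc.valid:
            continue
        ann_lo = nuc.radius + dr + params.droplet_clearance_px
        ann_hi = nuc.radius + params.ring_width - dr - 1.0
        if ann_hi <= ann_lo:
            continue
        # Draw ALL candidate droplets, then include by u < level: the same
        # seed yields a superset of droplets as the level rises (monotone
        # ground truth) and E[count] = level * max_droplets exactly.
        for _ in range(params.max_droplets_per_cell):
            u = rng.uniform()
            intensity = rng.uniform(*params.droplet_intensity)
            pos = None
            for _attempt in range(params.max_place_attempts):
                ang = rng.uniform(0, 2 * math.pi)
                rad = math.sqrt(rng.uniform(ann_lo ** 2, ann_hi ** 2))
                # snap to the pixel grid: every droplet then renders exactly
                # disk_area(radius) pixels, matching the summary-mode mean
                r0 = float(round(nuc.center[0] + rad * math.sin(ang)))
                c0 = float(round(nuc.center[1] + rad * math.cos(ang)))
                snapped = math.hypot(r0 - nuc.center[0], c0 - nuc.center[1])
                if not (ann_lo - 0.75 <= snapped <= ann_hi + 0.75):
                    continue
                # nearest-nucleus ownership must hold with margin
                d_owner = math.hypot(r0 - nuc.center[0], c0 - nuc.center[1]) - nuc.radius
                ok = all(
                    math.hypot(r0 - o.center[0], c0 - o.center[1]) - o.radius
                    > d_owner + 2.0
                    for j, o in enumerate(nuclei)
                    if j != idx
                )
                if ok and all(
                    math.hypot(r0 - a, c0 - b) >= min_drop_sep for a, b in placed
                ):
                    pos = (r0, c0)
                    break
            if pos is None:
                continue  # overcrowded annulus: skip this candidate (rare)
            placed.append(pos)
            if u < level:
                droplets.append(Droplet(pos, dr, intensity, owner=idx))
    return droplets


def generate_field(
    params: FieldParams | None = None, seed: int = 0
) -> tuple[FieldImage, FieldTruth]:
    """Render one two-channel field and its ground truth.

    Channel 1 (nuclear) holds Gaussian-tapered nucleus disks over a flat
    background; channel 2 (lipid) holds uniform droplet disks restricted to
    an annulus of ``ring_width`` around their owner nucleus. Identical
    (params, seed) give bit-identical rasters.
    """
    params = params or FieldParams()
    h, w = params.shape
    if h < 64 or w < 64:
        raise ValueError("image size must be at least 64x64 px")
    rng = np.random.default_rng(seed)
    nuclei = _place_nuclei(params, rng) if (params.n_nuclei + params.n_invalid) else []
    droplets = _place_droplets(params, nuclei, rng)

    ch1 = np.full(params.shape, params.background[0], dtype=float)
    ch2 = np.full(params.shape, params.background[1], dtype=float)
    for nuc in nuclei:
        _render_nucleus(ch1, nuc, params.taper_px)
    for d in droplets:
        d.area_px = _render_droplet(ch2, d)

    if params.poisson_noise:
        ch1 = rng.poisson(np.clip(ch1, 0, None)).astype(float)
        ch2 = rng.poisson(np.clip(ch2, 0, None)).astype(float)
    s1, s2 = params.noise_sigma
    if s1 > 0:
        ch1 = ch1 + rng.normal(0.0, s1, params.shape)
    if s2 > 0:
        ch2 = ch2 + rng.normal(0.0, s2, params.shape)

    truth = FieldTruth(
        nuclei=nuclei,
        droplets=droplets,
        background=params.background,
        noise_sigma=params.noise_sigma,
        shape=params.shape,
    )
    return FieldImage(nuclear=ch1, lipid=ch2), truth


# ---------------------------------------------------------------------------
# Plates

ROLE_STIMULATOR = "stimulator"
ROLE_NEUTRAL = "neutral"
ROLE_COMPOUND = "compound"
ROLE_EMPTY = "empty"

WELL_SUMMARY_COLUMNS = [
    "plate",
    "well",
    "row",
    "col",
    "role",
    "valid_cell_count",
    "iss_mean",
    "spot_count_mean",
    "spot_area_mean",
    "n_fields",
    "low_cell_flag",
]


@dataclass
class PlateSpec:
    """Layout and per-well true effects of one 384-well plate.

    Control columns are full single-role columns: the stimulator control
    (maximal lipid accumulation, inhibition 0) in ``stim_col`` and the
    neutral control (no induction, inhibition 1) in ``neut_col``; 1-based
    column numbers, default 11 and 12. ``inhibition`` and ``cell_loss`` map
    well ids to fractional effects in [0, 1] for compound wells.
    """

    n_rows: int = 16
    n_cols: int = 24
    stim_col: int = 11
    neut_col: int = 12
    inhibition: dict[str, float] = field(default_factory=dict)
    cell_loss: dict[str, float] = field(default_factory=dict)
    empty_wells: frozenset[str] = frozenset()
    plate_id: str = "P1"

    def __post_init__(self):
        if self.stim_col == self.neut_col:
            raise ValueError("control columns must differ")
        for w, v in list(self.inhibition.items()) + list(self.cell_loss.items()):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"effect for well {w} outside [0,1]: {v}")

    def role(self, row: int, col: int) -> str:
        wid = well_id(row, col)
        if wid in self.empty_wells:
            return ROLE_EMPTY
        if col + 1 == self.stim_col:
            return ROLE_STIMULATOR
        if col + 1 == self.neut_col:
            return ROLE_NEUTRAL
        return ROLE_COMPOUND

    def well_effects(self, row: int, col: int) -> tuple[float, float]:
        """(inhibition, cell_loss) for a well; controls are fixed by role."""
        role = self.role(row, col)
        wid = well_id(row, col)
        if role == ROLE_STIMULATOR:
            return 0.0, 0.0
        if role == ROLE_NEUTRAL:
            return 1.0, 0.0
        return self.inhibition.get(wid, 0.0), self.cell_loss.get(wid, 0.0)

    def compound_wells(self) -> list[str]:
        return [
            well_id(r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if self.role(r, c) == ROLE_COMPOUND
        ]

    @classmethod
    def with_spikes(
        cls,
        n_active: int = 5,
        active_inhibition: float = 0.8,
        n_toxic: int = 3,
        toxic_cell_loss: float = 0.7,
        seed: int = 0,
        **kwargs,
    ) -> "PlateSpec":
        """A plate with randomly placed active and cytotoxic compound wells."""
        spec = cls(**kwargs)
        rng = np.random.default_rng(seed)
        wells = spec.compound_wells()
        picks = rng.choice(len(wells), size=n_active + n_toxic, replace=False)
        spec.inhibition = {wells[i]: active_inhibition for i in picks[:n_active]}
        spec.cell_loss = {wells[i]: toxic_cell_loss for i in picks[n_active:]}
        return spec

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                inh, loss = self.well_effects(r, c)
                rows.append(
                    {
                        "plate": self.plate_id,
                        "well": well_id(r, c),
                        "row": r,
                        "col": c,
                        "role": self.role(r, c),
                        "inhibition": inh,
                        "cell_loss": loss,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PlateGenParams:
    """Generative conditions shared by summary- and image-level plate modes.

    The per-cell integrated spot signal of a well at steatosis level ``s``
    is ``s * max_droplets * droplet_area * droplet_intensity`` in both modes
    (summary mode draws well noise around that mean; image mode realizes it
    droplet by droplet). ``neutral_level`` is the residual lipid staining of
    uninduced wells as a fraction of the stimulator level. Well-level noise
    is multiplicative log-normal with unit mean.
    """

    cells_per_well: int = 900
    fields_per_well: int = 6
    cell_count_target: int = 600
    max_droplets_per_cell: int = 12
    droplet_radius: float = 2.0
    droplet_intensity: float = 300.0
    neutral_level: float = 0.03
    cv_iss: float = 0.08
    cv_cells: float = 0.05
    cv_spots: float = 0.08

    @property
    def droplet_area(self) -> int:
        return disk_area(self.droplet_radius)

    @property
    def iss_per_cell_stim(self) -> float:
        return self.max_droplets_per_cell * self.droplet_area * self.droplet_intensity

    def steatosis(self, inhibition: float) -> float:
        return self.neutral_level + (1.0 - inhibition) * (1.0 - self.neutral_level)

    def well_means(self, inhibition: float, cell_loss: float) -> dict[str, float]:
        s = self.steatosis(inhibition)
        return {
            "iss_mean": s * self.iss_per_cell_stim,
            "spot_count_mean": s * self.max_droplets_per_cell,
            "spot_area_mean": s * self.max_droplets_per_cell * self.droplet_area,
            "valid_cell_count": self.cells_per_well * (1.0 - cell_loss),
        }


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise factor with coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(-sigma * sigma / 2.0, sigma)))


def generate_plate(
    spec: PlateSpec,
    params: PlateGenParams | None = None,
    seed: int = 0,
    image_level: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one plate, returning (well summary table, truth table).

    Summary mode draws per-well aggregates directly from the generative
    means (fast; 36-plate campaigns run in seconds). Image mode renders and
    quantifies small fields per well and is reserved for small problems; use
    :func:`generate_well_images` plus the imaging module for that path — here
    ``image_level=True`` raises to keep the fast path unambiguous.
    """
    if image_level:
        raise ValueError(
            "generate_plate is summary-level; render wells with generate_well_images"
        )
    params = params or PlateGenParams()
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            role = spec.role(r, c)
            if role == ROLE_EMPTY:
                continue
            inh, loss = spec.well_effects(r, c)
            means = params.well_means(inh, loss)
            cells = means["valid_cell_count"] * _lognormal_factor(rng, params.cv_cells)
            cells = int(round(cells))
            iss = means["iss_mean"] * _lognormal_factor(rng, params.cv_iss)
            spots = means["spot_count_mean"] * _lognormal_factor(rng, params.cv_spots)
            area = spots * params.droplet_area
            rows.append(
                {
                    "plate": spec.plate_id,
                    "well": well_id(r, c),
                    "row": r,
                    "col": c,
                    "role": role,
                    "valid_cell_count": cells,
                    "iss_mean": iss,
                    "spot_count_mean": spots,
                    "spot_area_mean": area,
                    "n_fields": params.fields_per_well,
                    "low_cell_flag": cells < params.cell_count_target,
                }
            )
    return pd.DataFrame(rows, columns=WELL_SUMMARY_COLUMNS), spec.truth_table()


def generate_well_images(
    inhibition: float,
    cell_loss: float,
    params: PlateGenParams | None = None,
    field_params: FieldParams | None = None,
    seed: int = 0,
) -> list[tuple[FieldImage, FieldTruth]]:
    """Render the fields of one well at the plate-mode generative means.

    Field geometry (size, radii, noise) comes from ``field_params``; droplet
    load and cell count come from the well effects so that image-level well
    means match :func:`generate_plate` summary means. Cells are included with
    probability ``1 - cell_loss`` so the expected count is exact.
    """
    params = params or PlateGenParams()
    base = field_params or FieldParams()
    per_field = int(round(params.cells_per_well / params.fields_per_well))
    fields = []
    rng = np.random.default_rng(seed)
    for f in range(params.fields_per_well):
        n = int(np.random.default_rng(seed * 10007 + f).binomial(per_field, 1.0 - cell_loss))
        fp = FieldParams(
            shape=base.shape,
            n_nuclei=n,
            nucleus_radius=base.nucleus_radius,
            nucleus_peak=base.nucleus_peak,
            taper_px=base.taper_px,
            background=base.background,
            noise_sigma=base.noise_sigma,
            steatosis_level=params.steatosis(inhibition),
            max_droplets_per_cell=params.max_droplets_per_cell,
            droplet_radius=params.droplet_radius,
            droplet_intensity=(params.droplet_intensity, params.droplet_intensity),
            ring_width=base.ring_width,
        )
        fields.append(generate_field(fp, seed=int(rng.integers(0, 2 ** 31 - 1))))
    return fields


# ---------------------------------------------------------------------------
# Dose-response series


def six_point_range(top: float = 10e-6, bottom: float = 0.625e-6) -> np.ndarray:
    """Six-point geometric concentration series, 10 uM down to 0.625 uM."""
    return np.geomspace(top, bottom, 6)


def ten_point_range(top: float = 10e-6, step: float = math.sqrt(10.0)) -> np.ndarray:
    """Ten-point half-log dilution series starting at 10 uM."""
    return top / step ** np.arange(10)


@dataclass
class DoseSeriesSpec:
    """True 4PL parameters and sampling plan for one dose-response series."""

    top: float = 100.0
    bottom: float = 0.0
    ic50: float = 1e-6
    hill: float = 1.0
    concentrations: np.ndarray = field(default_factory=ten_point_range)
    replicates: int = 3
    cv: float = 0.1

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        self.concentrations = np.sort(conc)
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.cv < 0:
            raise ValueError("CV must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def generate_dose_series(spec: DoseSeriesSpec, seed: int = 0) -> pd.DataFrame:
    """Sample replicate responses: 4PL(conc) times unit-mean log-normal noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for conc in spec.concentrations:
        y = four_pl(conc, spec.top, spec.bottom, spec.ic50, spec.hill)
        for rep in range(spec.replicates):
            rows.append(
                {
                    "concentration": float(conc),
                    "replicate": rep,
                    "response": float(y * _lognormal_factor(rng, spec.cv)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Cq tables


@dataclass
class CqSpec:
    """Planted expression effects for a qPCR experiment.

    ``log2_fold_changes`` maps gene -> treatment group -> true log2 fold
    change versus the control group; reference genes have no entry (true
    fold change 1 everywhere). Cq values follow
    ``Cq = baseline - log2(fold) + noise``: a gene expressed 2-fold higher
    amplifies one cycle earlier.
    """

    genes: list[str] = field(default_factory=lambda: ["DGAT2", "CDK2", "CEBPA"])
    reference_genes: list[str] = field(default_factory=lambda: ["HPRT1", "GAPDH"])
    groups: list[str] = field(default_factory=lambda: ["TGFA", "TGFA+CPD"])
    control_group: str = "TGFA"
    log2_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    replicates: int = 3
    noise_sd: float = 0.1
    baseline_cq: float = 24.0

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.control_group not in self.groups:
            raise ValueError("control group missing from groups")
        for gene in self.log2_fold_changes:
            if gene in self.reference_genes:
                raise ValueError(f"reference gene {gene} cannot carry an effect")


def generate_cq_table(spec: CqSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate a Cq table with columns (sample, group, gene, replicate, cq)."""
    rng = np.random.default_rng(seed)
    rows = []
    for group in spec.groups:
        for rep in range(spec.replicates):
            sample = f"{group}_s{rep + 1}"
            for gene in list(spec.genes) + list(spec.reference_genes):
                lfc = 0.0
                if group != spec.control_group:
                    lfc = spec.log2_fold_changes.get(gene, {}).get(group, 0.0)
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "cq": spec.baseline_cq - lfc + noise,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Compound libraries


def generate_compound_set(
    n: int,
    seed: int = 0,
    n_families: int = 3,
    n_bits: int = 2048,
    bits_on: int = 64,
    mutation_bits: int = 8,
    potency_mean: float = 8.0,
    potency_sd: float = 0.4,
    off_target_mean: float = 5.5,
):
    """Generate a clustered fingerprint library with pXC50 annotations.

    Compounds fall into ``n_families`` structural families: each family has a
    random parent fingerprint and members differ from it by ``mutation_bits``
    bit swaps, so within-family Tanimoto distances are well below
    between-family distances. Each family hits its own pair of targets with
    potencies above the conventional 7.0 cutoff and shows weak off-target
    activity elsewhere.

    Returns ``(fingerprints, activities, family_labels, class_map)`` where
    ``fingerprints`` is a :class:`steatoscreen.chem.FingerprintSet`,
    ``activities`` has columns (compound, target, source, value), and
    ``class_map`` maps targets to family target-class names.
    """
    from .chem import FingerprintSet

    if n < 2:
        raise ValueError("need at least 2 compounds")
    rng = np.random.default_rng(seed)
    parents = [
        rng.choice(n_bits, size=bits_on, replace=False) for _ in range(n_families)
    ]
    ids, labels = [], []
    fps = np.zeros((n, n_bits), dtype=bool)
    for i in range(n):
        fam = i % n_families
        bits = set(parents[fam].tolist())
        drop = rng.choice(sorted(bits), size=min(mutation_bits, len(bits)), replace=False)
        bits -= set(drop.tolist())
        while len(bits) < bits_on:
            bits.add(int(rng.integers(0, n_bits)))
        fps[i, sorted(bits)] = True
        ids.append(f"C{i + 1}")
        labels.append(fam)

    targets = {f: [f"FAM{f}_T1", f"FAM{f}_T2"] for f in range(n_families)}
    class_map = {t: f"class_{f}" for f, ts in targets.items() for t in ts}
    act_rows = []
    for i, cid in enumerate(ids):
        fam = labels[i]
        for t in targets[fam]:
            act_rows.append(
                {
                    "compound": cid,
                    "target": t,
                    "source": "internal",
                    "value": float(max(rng.normal(potency_mean, potency_sd), 7.2)),
                }
            )
        other = (fam + 1) % n_families
        act_rows.append(
            {
                "compound": cid,
                "target": targets[other][0],
                "source": "internal",
                "value": float(min(rng.normal(off_target_mean, 0.5), 6.8)),
            }
        )
    activities = pd.DataFrame(act_rows)
    return (
        FingerprintSet(ids=ids, bits=fps, provenance="precomputed"),
        activities,
        np.array(labels),
        class_map,
    )
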