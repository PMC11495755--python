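"""Marked point-process simulator for multiplexed-imaging tissue cores.

Generates cohorts of circular 1 mm tissue-microarray cores with the spatial
structure the downstream analysis is designed to detect:

* background cells of each phenotype as a homogeneous Poisson process on the
  core disc, at configurable intensities (cells/mm^2);
* blood vessels as uniform random chords through the disc, with endothelial
  cells as a Poisson process along each chord;
* perivascular macrophages (PVMs) placed at a vessel-attached endothelial
  anchor plus an isotropic Gaussian displacement (default sd 8 um, so most
  PVMs fall within 20 um of endothelium);
* immune aggregates: Gaussian clouds of immune cells centred on a PVM, whose
  per-core rate can be enriched in the tumor region (the planted signal for
  recovery testing).

Marker intensities are phenotype prototype means plus independent Gaussian
noise truncated at zero.  Each core draws from its own RNG stream derived
from ``(seed, image_id)``, so a cohort is reproducible regardless of the
order cores are generated in.

Background intensities are region-independent by default: the emulated
biology is one where cell *densities* are largely consistent across regions
while *neighborhood structure* (the perivascular niche) differs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_tables import DEFAULT_CORE_AREA_MM2, REGION_CLASSES, CellTable, RegionMetadata
from .util import rng_for

PHENOTYPE_ROLES = ("background", "endothelial", "perivascular_macrophage", "aggregate_member")

#: 39-channel panel emulating an IMC antibody panel for liver tumor tissue.
DEFAULT_MARKERS = (
    "CD45", "CD3", "CD4", "CD8A", "CD45RO", "CD69", "FOXP3", "CD20", "CD56",
    "CD11B", "CD11C", "CD14", "CD16", "CD68", "CD206", "FXIIIA", "HLA_DR",
    "CD86", "PD_L1", "PD_1", "TBET", "GRANZYME_B", "KI67", "CD31", "CD34",
    "VEGFA", "ASMA", "PANCK", "HEPPAR1", "ECADHERIN", "VIMENTIN",
    "COLLAGEN_I", "CD15", "CD38", "CD141", "CD103", "TIM3", "LAG3", "DNA_IR",
)


@dataclass(frozen=True)
class PhenotypeSpec:
    """A cell phenotype: a name, a marker-prototype vector and a structural role."""

    name: str
    marker_means: Mapping[str, float]
    role: str = "background"

    def __post_init__(self):
        if self.role not in PHENOTYPE_ROLES:
            raise ConfigError(f"unknown phenotype role {self.role!r}")


def _proto(positive, markers=DEFAULT_MARKERS, high=8.0, base=0.5):
    return {m: (high if m in positive else base) for m in markers}


def default_phenotypes() -> list[PhenotypeSpec]:
    """The default 11-phenotype panel (liver parenchyma, stroma, immune cells,
    CD34+ endothelium, VEGFA+ perivascular macrophages and aggregate members)."""
    return [
        PhenotypeSpec("hepatocyte", _proto({"HEPPAR1", "ECADHERIN", "PANCK"})),
        PhenotypeSpec("stromal", _proto({"ASMA", "VIMENTIN", "COLLAGEN_I"})),
        PhenotypeSpec("b_cell", _proto({"CD45", "CD20", "HLA_DR"})),
        PhenotypeSpec("t_cell", _proto({"CD45", "CD3", "CD4"})),
        PhenotypeSpec("kupffer_macrophage", _proto({"CD45", "CD68", "CD206", "CD11B"})),
        PhenotypeSpec(
            "endothelial_cd34", _proto({"CD31", "CD34", "VIMENTIN"}), role="endothelial"
        ),
        PhenotypeSpec(
            "pvm",
            _proto({"CD45", "CD14", "CD16", "CD68", "CD206", "FXIIIA", "HLA_DR", "CD86", "VEGFA"}),
            role="perivascular_macrophage",
        ),
        PhenotypeSpec(
            "trm_cd4",
            _proto({"CD45", "CD3", "CD4", "CD45RO", "CD69"}),
            role="aggregate_member",
        ),
        PhenotypeSpec(
            "trm_cd8",
            _proto({"CD45", "CD3", "CD8A", "CD45RO", "CD69", "TBET", "PD_L1"}),
            role="aggregate_member",
        ),
        PhenotypeSpec(
            "dendritic_cell",
            _proto({"CD45", "CD11C", "HLA_DR", "CD86"}),
            role="aggregate_member",
        ),
        PhenotypeSpec(
            "aggregate_macrophage",
            _proto({"CD45", "CD14", "CD68", "CD16", "FXIIIA"}),
            role="aggregate_member",
        ),
    ]


def default_background_intensity() -> dict[str, float]:
    """Default background intensities, cells/mm^2 (region-independent)."""
    return {
        "hepatocyte": 300.0,
        "stromal": 40.0,
        "b_cell": 30.0,
        "t_cell": 100.0,
        "kupffer_macrophage": 50.0,
        "endothelial_cd34": 0.0,
        "pvm": 0.0,
        "trm_cd4": 50.0,
        "trm_cd8": 30.0,
        "dendritic_cell": 15.0,
        "aggregate_macrophage": 25.0,
    }


@dataclass
class NicheConfig:
    """Parameters of the planted perivascular niche.

    ``pvm_per_vessel_rate`` is the expected PVM count for a full-diameter
    vessel (scaled by chord length).  ``aggregate_rate_by_region`` is the
    expected number of immune aggregates per core; the tumor region's rate is
    additionally multiplied by ``enrichment_multiplier_tumor`` — this is the
    planted region effect.  Each aggregate is a Gaussian cloud (sd
    ``aggregate_spread_um``) of cells of a single aggregate-member phenotype,
    centred on a randomly chosen PVM.
    """

    pvm_per_vessel_rate: float = 3.0
    pvm_distance_sd_um: float = 8.0
    aggregate_rate_by_region: dict[str, float] = field(
        default_factory=lambda: {r: 2.0 for r in REGION_CLASSES}
    )
    aggregate_spread_um: float = 12.0
    aggregate_members_mean: float = 6.0
    enrichment_multiplier_tumor: float = 2.0

    def __post_init__(self):
        vals = [
            self.pvm_per_vessel_rate,
            self.pvm_distance_sd_um,
            self.aggregate_spread_um,
            self.aggregate_members_mean,
            self.enrichment_multiplier_tumor,
            *self.aggregate_rate_by_region.values(),
        ]
        if any(v < 0 for v in vals):
            raise ConfigError("niche rates and scales must be non-negative")


@dataclass
class SimConfig:
    """Cohort design + generative parameters.

    Defaults emulate the study design this package targets: 16 patients, each
    with nontumor / invasive-margin / tumor regions sampled as three replicate
    1 mm circular cores, a 39-channel marker panel and 11 phenotypes.
    """

    n_patients: int = 16
    regions: tuple[str, ...] = REGION_CLASSES
    replicates_per_region: int = 3
    core_diameter_um: float = 1000.0
    phenotypes: list[PhenotypeSpec] = field(default_factory=default_phenotypes)
    vessels_per_core: dict[str, float] = field(
        default_factory=lambda: {r: 3.0 for r in REGION_CLASSES}
    )
    endothelial_per_vessel_rate: float = 25.0
    niche: NicheConfig = field(default_factory=NicheConfig)
    background_intensity: dict[str, float | dict[str, float]] = field(
        default_factory=default_background_intensity
    )
    marker_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.phenotypes:
            raise ConfigError("at least one phenotype is required")
        names = [p.name for p in self.phenotypes]
        if len(set(names)) != len(names):
            raise ConfigError("phenotype names must be unique")
        marker_sets = {tuple(sorted(p.marker_means)) for p in self.phenotypes}
        if len(marker_sets) != 1:
            raise ConfigError("all phenotypes must share one marker set")
        if self.marker_noise_sd < 0:
            raise ConfigError("marker_noise_sd must be non-negative")
        if any(v < 0 for v in self.vessels_per_core.values()):
            raise ConfigError("vessel rates must be non-negative")

    # -- helpers ---------------------------------------------------------
    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.phenotypes[0].marker_means)

    def phenotype_by_role(self, role: str) -> list[PhenotypeSpec]:
        return [p for p in self.phenotypes if p.role == role]

    def intensity(self, phenotype: str, region: str) -> float:
        v = self.background_intensity.get(phenotype, 0.0)
        if isinstance(v, Mapping):
            return float(v.get(region, 0.0))
        return float(v)

    def aggregate_rate(self, region: str) -> float:
        rate = self.niche.aggregate_rate_by_region.get(region, 0.0)
        if region == "tumor":
            rate *= self.niche.enrichment_multiplier_tumor
        return rate

    def nullified(self) -> "SimConfig":
        """A copy with identical generative law in every region class."""
        ref = self.regions[0]
        null_niche = replace(
            self.niche,
            aggregate_rate_by_region={
                r: self.niche.aggregate_rate_by_region.get(ref, 0.0) for r in self.regions
            },
            enrichment_multiplier_tumor=1.0,
        )
        bg = {}
        for phen, v in self.background_intensity.items():
            bg[phen] = float(v.get(ref, 0.0)) if isinstance(v, Mapping) else float(v)
        return replace(
            self,
            niche=null_niche,
            vessels_per_core={r: self.vessels_per_core.get(ref, 0.0) for r in self.regions},
            background_intensity=bg,
        )


@dataclass
class GroundTruth:
    """Simulator oracle: true labels, niche membership and planted effects.

    ``cells`` has one row per generated cell (cell_id, image_id, phenotype,
    niche_member).  ``vessels`` maps image_id to the list of vessel chord
    endpoints.  ``designated_pairs`` are the directed (aggregate-member ->
    PVM) phenotype pairs whose neighborhood counts carry the planted
    tumor-region enrichment, whose expected multiplier per region is in
    ``region_effects``.
    """

    cells: pd.DataFrame
    vessels: dict[str, list[tuple[tuple[float, float], tuple[float, float]]]]
    designated_pairs: list[tuple[str, str]]
    region_effects: dict[str, float]

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    def designated_features(self) -> list[str]:
        """Feature-matrix column names carrying the planted interaction.

        Both directed neighborhood statistics of each planted (member, PVM)
        pair: the PVM -> member direction carries the exact multiplicative
        excess (pair counts scale with the aggregate rate while the PVM count
        does not), the member -> PVM direction the niche-fraction excess.
        """
        feats = []
        for member, pvm in self.designated_pairs:
            feats.append(f"neigh_{member}_{pvm}")
            feats.append(f"neigh_{pvm}_{member}")
        return feats


def cohort_metadata(config: SimConfig) -> RegionMetadata:
    """Enumerate the cohort's cores: one image per patient x region x replicate."""
    area = math.pi * (config.core_diameter_um / 2000.0) ** 2  # mm^2
    rows = []
    for p in range(1, config.n_patients + 1):
        patient = f"P{p:02d}"
        for region in config.regions:
            for rep in range(1, config.replicates_per_region + 1):
                rows.append(
                    {
                        "image_id": f"{patient}_{region}_r{rep}",
                        "patient_id": patient,
                        "region_class": region,
                        "replicate": rep,
                        "area_mm2": area,
                    }
                )
    return RegionMetadata(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# geometry helpers (single core, centre (R, R), radius R)
# ---------------------------------------------------------------------------

def _uniform_disc(rng, n, radius, centre):
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([centre[0] + r * np.cos(th), centre[1] + r * np.sin(th)])


def _random_chord(rng, radius, centre):
    """A uniform random chord: random direction + uniform perpendicular offset."""
    phi = rng.uniform(0.0, 2.0 * np.pi)
    h = rng.uniform(-radius, radius)
    half = math.sqrt(max(radius**2 - h**2, 0.0))
    ux, uy = math.cos(phi), math.sin(phi)      # chord direction
    nx, ny = -uy, ux                           # unit normal
    mx, my = centre[0] + h * nx, centre[1] + h * ny
    p1 = (mx - half * ux, my - half * uy)
    p2 = (mx + half * ux, my + half * uy)
    return p1, p2, 2.0 * half


def _inside(points, radius, centre):
    d2 = (points[:, 0] - centre[0]) ** 2 + (points[:, 1] - centre[1]) ** 2
    return d2 <= radius**2


def _gaussian_around(rng, anchors, sd, radius, centre, max_tries=200):
    """Anchor + isotropic Gaussian displacement, resampled to stay on the disc."""
    pts = anchors + rng.normal(0.0, sd, size=anchors.shape) if sd > 0 else anchors.copy()
    for _ in range(max_tries):
        bad = ~_inside(pts, radius, centre)
        if not bad.any():
            break
        pts[bad] = anchors[bad] + rng.normal(0.0, sd, size=(int(bad.sum()), 2))
    else:  # pragma: no cover - anchors are always inside, loop terminates early
        pts[bad] = anchors[bad]
    return pts


# ---------------------------------------------------------------------------
# core + cohort generation
# ---------------------------------------------------------------------------

def _simulate_core(config: SimConfig, image_id: str, region: str):
    """Generate one core; returns (positions, phenotype names, niche flags, vessels)."""
    rng = rng_for(config.seed, image_id)
    radius = config.core_diameter_um / 2.0
    centre = (radius, radius)
    area_mm2 = math.pi * (radius / 1000.0) ** 2

    pos_blocks, phen_blocks, niche_blocks = [], [], []

    def emit(points, phenotype, niche):
        pos_blocks.append(points)
        phen_blocks.extend([phenotype] * len(points))
        niche_blocks.extend([niche] * len(points))

    # background cells: homogeneous Poisson per phenotype
    for spec in config.phenotypes:
        lam = config.intensity(spec.name, region) * area_mm2
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n:
            emit(_uniform_disc(rng, n, radius, centre), spec.name, False)

    # vessels and vessel-bound populations
    endo = config.phenotype_by_role("endothelial")
    pvm = config.phenotype_by_role("perivascular_macrophage")
    members = config.phenotype_by_role("aggregate_member")
    vessels = []
    pvm_positions = []
    n_vessels = int(rng.poisson(config.vessels_per_core.get(region, 0.0)))
    for _ in range(n_vessels):
        p1, p2, length = _random_chord(rng, radius, centre)
        vessels.append((p1, p2))
        frac = length / config.core_diameter_um
        # endothelial cells: Poisson along the chord, rate scaled by length
        if endo:
            n_ec = int(rng.poisson(config.endothelial_per_vessel_rate * frac))
            if n_ec:
                t = rng.uniform(size=n_ec)
                base = np.outer(1 - t, p1) + np.outer(t, p2)
                jitter = rng.normal(0.0, 2.0, size=(n_ec, 2))
                pts = base + jitter
                pts[~_inside(pts, radius, centre)] = base[~_inside(pts, radius, centre)]
                ec_pts = pts
                for spec in endo:  # single endothelial phenotype in default panel
                    emit(ec_pts, spec.name, True)
                    break
            else:
                ec_pts = np.empty((0, 2))
        else:
            ec_pts = np.empty((0, 2))
        # PVMs: anchored at a random endothelial cell of this vessel
        if pvm and len(ec_pts):
            n_pvm = int(rng.poisson(config.niche.pvm_per_vessel_rate * frac))
            if n_pvm:
                anchors = ec_pts[rng.integers(0, len(ec_pts), size=n_pvm)]
                pts = _gaussian_around(
                    rng, anchors, config.niche.pvm_distance_sd_um, radius, centre
                )
                emit(pts, pvm[0].name, True)
                pvm_positions.append(pts)

    pvm_positions = (
        np.concatenate(pvm_positions) if pvm_positions else np.empty((0, 2))
    )

    # immune aggregates: Gaussian clouds of one member phenotype around a PVM
    if members and len(pvm_positions):
        n_agg = int(rng.poisson(config.aggregate_rate(region)))
        for _ in range(n_agg):
            centre_pt = pvm_positions[rng.integers(0, len(pvm_positions))]
            spec = members[rng.integers(0, len(members))]
            m = int(rng.poisson(config.niche.aggregate_members_mean))
            if m:
                anchors = np.tile(centre_pt, (m, 1))
                pts = _gaussian_around(
                    rng, anchors, config.niche.aggregate_spread_um, radius, centre
                )
                emit(pts, spec.name, True)

    if pos_blocks:
        positions = np.concatenate(pos_blocks)
    else:
        positions = np.empty((0, 2))
    phenotypes = np.array(phen_blocks, dtype=object)
    niche = np.array(niche_blocks, dtype=bool)

    # marker intensities: prototype mean + truncated Gaussian noise
    markers = config.markers
    proto = {p.name: np.array([p.marker_means[m] for m in markers]) for p in config.phenotypes}
    intensities = np.empty((len(positions), len(markers)))
    for i, ph in enumerate(phenotypes):
        intensities[i] = proto[ph]
    if config.marker_noise_sd > 0 and len(positions):
        intensities = intensities + rng.normal(
            0.0, config.marker_noise_sd, size=intensities.shape
        )
    np.clip(intensities, 0.0, None, out=intensities)
    return positions, phenotypes, niche, intensities, vessels


def simulate_cohort(config: SimConfig) -> tuple[CellTable, RegionMetadata, GroundTruth]:
    """Simulate a full cohort of cores.

    Returns the cell table (with a ``phenotype`` column holding the true
    labels), the region metadata and the ground truth for recovery testing.
    Identical config (including seed) gives identical output.
    """
    meta = cohort_metadata(config)
    markers = config.markers
    frames, gt_rows, vessels_all = [], [], {}
    for _, row in meta.data.iterrows():
        image_id, region = row["image_id"], row["region_class"]
        pos, phen, niche, inten, vessels = _simulate_core(config, image_id, region)
        n = len(pos)
        cell_ids = [f"{image_id}_c{i:05d}" for i in range(n)]
        df = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "image_id": image_id,
                "x_um": np.round(pos[:, 0], 3) if n else pos[:, 0],
                "y_um": np.round(pos[:, 1], 3) if n else pos[:, 1],
            }
        )
        for j, m in enumerate(markers):
            df[m] = np.round(inten[:, j], 4)
        df["phenotype"] = phen
        frames.append(df)
        gt_rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_ids,
                    "image_id": image_id,
                    "phenotype": phen,
                    "niche_member": niche,
                }
            )
        )
        vessels_all[image_id] = vessels

    cells = CellTable(pd.concat(frames, ignore_index=True), markers)
    pvm_specs = config.phenotype_by_role("perivascular_macrophage")
    members = config.phenotype_by_role("aggregate_member")
    designated = (
        [(m.name, pvm_specs[0].name) for m in members] if pvm_specs and members else []
    )
    effects = {
        r: (config.niche.enrichment_multiplier_tumor if r == "tumor" else 1.0)
        for r in config.regions
    }
    truth = GroundTruth(
        cells=pd.concat(gt_rows, ignore_index=True),
        vessels=vessels_all,
        designated_pairs=designated,
        region_effects=effects,
    )
    return cells, meta, truth


def simulate_null_cohort(config: SimConfig) -> tuple[CellTable, RegionMetadata, GroundTruth]:
    """Simulate a cohort whose region labels carry no information.

    The generative law of ``config``'s first region class is applied to every
    region, and the tumor enrichment multiplier is forced to 1, so any
    apparent region effect downstream is sampling noise.  Used to calibrate
    the permutation tests' type-I error.
    """
    return simulate_cohort(config.nullified())


# ---------------------------------------------------------------------------
# small scaled-down configs (for calibration studies and quick runs)
# ---------------------------------------------------------------------------

def make_phenotype_panel(
    n_phenotypes: int,
    n_markers: int | None = None,
    high: float = 8.0,
    base: float = 0.5,
) -> list[PhenotypeSpec]:
    """A synthetic panel of well-spaced prototypes for scaled-down cohorts.

    The last three phenotypes take the endothelial, PVM and aggregate-member
    roles (when ``n_phenotypes`` >= 4); phenotype ``i`` is high on markers
    ``2i`` and ``2i+1``.
    """
    if n_phenotypes < 1:
        raise ConfigError("need at least one phenotype")
    if n_markers is None:
        n_markers = 2 * n_phenotypes
    markers = [f"M{j:02d}" for j in range(n_markers)]
    roles = ["background"] * n_phenotypes
    if n_phenotypes >= 4:
        roles[-3], roles[-2], roles[-1] = (
            "endothelial",
            "perivascular_macrophage",
            "aggregate_member",
        )
    specs = []
    for i in range(n_phenotypes):
        pos = {markers[(2 * i) % n_markers], markers[(2 * i + 1) % n_markers]}
        specs.append(
            PhenotypeSpec(f"phen{i:02d}", _proto(pos, markers, high, base), role=roles[i])
        )
    return specs


def small_config(
    n_patients: int = 8,
    n_phenotypes: int = 5,
    replicates_per_region: int = 1,
    seed: int = 0,
) -> SimConfig:
    """A scaled-down cohort config used for calibration studies."""
    phenotypes = make_phenotype_panel(n_phenotypes)
    bg: dict[str, float | dict[str, float]] = {}
    base_rates = [300.0, 100.0, 60.0, 40.0, 30.0]
    bg_idx = 0
    for spec in phenotypes:
        if spec.role == "background":
            bg[spec.name] = base_rates[bg_idx % len(base_rates)]
            bg_idx += 1
        elif spec.role == "aggregate_member":
            bg[spec.name] = 50.0
        else:
            bg[spec.name] = 0.0
    return SimConfig(
        n_patients=n_patients,
        replicates_per_region=replicates_per_region,
        phenotypes=phenotypes,
        background_intensity=bg,
        seed=seed,
    )
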