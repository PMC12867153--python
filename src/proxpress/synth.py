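"""Synthetic-tissue and synthetic-count generators with planted ground truth.

The tissue generator emulates the geometry of a tumor tissue-microarray core:
cancer cells grow in clustered nests (a Thomas-style cluster process — nest
centers uniform over the field, offspring displaced by an isotropic Gaussian),
while each immune population mixes a spatially uniform component with an
"attracted" component placed near cancer cells. The attraction strength
``lambda`` of a population sets the mixing weight ``lambda / (1 + lambda)``;
attracted cells are displaced from a uniformly chosen cancer cell by an
isotropic exponential kernel whose scale is one cell diameter, so their
density decays with distance to the nearest cancer cell. A per-class
multiplier applied to ``lambda`` in the "resistant" group plants a group
difference that downstream neighborhood statistics must recover.

Marker intensities are lognormal: each cell class has an elevated log-mean on
its defining marker (epithelial markers for cancer cells) and the background
log-mean elsewhere. Everything is driven by one integer seed; identical
configurations produce bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geomx import CountMatrix

__all__ = [
    "ImmunePopulation",
    "SimConfig",
    "generate_tissue",
    "generate_cohort",
    "generate_counts",
]


@dataclass(frozen=True)
class ImmunePopulation:
    """One immune cell class: its defining marker doubles as the class name.

    ``attraction`` is the dimensionless strength lambda >= 0 of the pull
    toward cancer cells; 0 means complete spatial randomness.
    """

    name: str
    n_cells: int
    attraction: float
    marker_mean_log: float = 3.0
    marker_sd_log: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("immune population size must be positive")
        if self.attraction < 0:
            raise ValueError("attraction strength must be >= 0")
        if self.marker_sd_log < 0:
            raise ValueError("marker log-sd must be >= 0")


def _default_populations() -> tuple[ImmunePopulation, ...]:
    return (
        ImmunePopulation("CD8", 80, 2.0),
        ImmunePopulation("CD4", 80, 1.5),
        ImmunePopulation("CD20", 50, 0.5),
        ImmunePopulation("CD68", 60, 1.0),
        ImmunePopulation("FOXP3", 30, 1.0),
    )


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort.

    Lengths are in the same (arbitrary, micrometre-like) units as the cell
    coordinates; areas in squared units. The defaults describe a 600x600
    core with six cancer nests and five immune populations, and plant a
    five-fold CD8 attraction increase in the "resistant" group.
    """

    n_samples_per_group: int = 20
    field_size: tuple[float, float] = (600.0, 600.0)
    n_nests: int = 6
    nest_spread: float = 40.0
    n_cancer_cells: int = 300
    immune_populations: tuple[ImmunePopulation, ...] = field(
        default_factory=_default_populations
    )
    epithelial_markers: tuple[str, ...] = ("ECAD", "PANCK")
    pan_immune_marker: str = "CD45"
    pan_immune_mean_log: float = 3.0
    cancer_marker_mean_log: float = 3.0
    cancer_marker_sd_log: float = 0.5
    background_marker_mean_log: float = 0.0
    background_marker_sd_log: float = 0.5
    cell_area_mean: float = 80.0
    cell_area_sd: float = 20.0
    cell_area_floor: float = 5.0
    group_effect: dict[str, float] = field(default_factory=lambda: {"CD8": 5.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        if min(self.field_size) <= 0:
            raise ValueError("field extents must be positive")
        if self.n_nests <= 0 or self.n_cancer_cells <= 0:
            raise ValueError("nest and cancer-cell counts must be positive")
        if self.nest_spread <= 0:
            raise ValueError("nest spread must be positive")
        if not self.immune_populations:
            raise ValueError("at least one immune population is required")
        if self.cell_area_mean <= 0 or self.cell_area_floor <= 0:
            raise ValueError("cell areas must be positive")
        if any(m < 0 for m in self.group_effect.values()):
            raise ValueError("group-effect multipliers must be >= 0")
        self.immune_populations = tuple(
            p if isinstance(p, ImmunePopulation) else ImmunePopulation(**p)
            for p in self.immune_populations
        )

    @property
    def cell_diameter(self) -> float:
        """Nominal cell diameter implied by the mean area (area-equivalent)."""
        return 2.0 * float(np.sqrt(self.cell_area_mean / np.pi))

    def marker_names(self) -> list[str]:
        names = list(self.epithelial_markers)
        if self.pan_immune_marker:
            names.append(self.pan_immune_marker)
        names.extend(p.name for p in self.immune_populations)
        return names

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "field_size" in d:
            d["field_size"] = tuple(d["field_size"])
        if "immune_populations" in d:
            d["immune_populations"] = tuple(
                ImmunePopulation(**p) if isinstance(p, dict) else p
                for p in d["immune_populations"]
            )
        if "epithelial_markers" in d:
            d["epithelial_markers"] = tuple(d["epithelial_markers"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _rng(config: SimConfig, seed_offset: int) -> np.random.Generator:
    if seed_offset < 0:
        raise ValueError("seed_offset must be >= 0")
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(seed_offset,))
    )


def _truncated_areas(rng, n, mean, sd, floor):
    a = (floor - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_tissue(
    config: SimConfig, sample_id: str, group: str = "sensitive", seed_offset: int = 0
) -> pd.DataFrame:
    """Generate one synthetic core as a cell table.

    ``group`` selects whether the ``group_effect`` multipliers apply
    ("resistant") or not (any other label). ``seed_offset`` separates the
    random streams of samples sharing one config.
    """
    rng = _rng(config, seed_offset)
    fx, fy = config.field_size
    scale = config.cell_diameter  # attraction kernel scale: one cell diameter

    # Cancer nests: uniform centers, Gaussian offspring, clipped to the field.
    centers = rng.uniform((0, 0), (fx, fy), size=(config.n_nests, 2))
    assign = rng.integers(config.n_nests, size=config.n_cancer_cells)
    cancer_xy = centers[assign] + rng.normal(
        0.0, config.nest_spread, size=(config.n_cancer_cells, 2)
    )
    cancer_xy = np.clip(cancer_xy, (0, 0), (fx, fy))

    rows_xy = [cancer_xy]
    classes = ["cancer"] * config.n_cancer_cells
    for pop in config.immune_populations:
        lam = pop.attraction
        if group == "resistant":
            lam *= config.group_effect.get(pop.name, 1.0)
        w = lam / (1.0 + lam)
        attracted = rng.random(pop.n_cells) < w
        xy = rng.uniform((0, 0), (fx, fy), size=(pop.n_cells, 2))
        n_att = int(attracted.sum())
        if n_att:
            anchors = cancer_xy[rng.integers(config.n_cancer_cells, size=n_att)]
            r = rng.exponential(scale, size=n_att)
            theta = rng.uniform(0.0, 2 * np.pi, size=n_att)
            xy[attracted] = anchors + np.column_stack(
                (r * np.cos(theta), r * np.sin(theta))
            )
        xy = np.clip(xy, (0, 0), (fx, fy))
        rows_xy.append(xy)
        classes.extend([pop.name] * pop.n_cells)

    xy = np.vstack(rows_xy)
    n = len(xy)
    areas = _truncated_areas(
        rng, n, config.cell_area_mean, config.cell_area_sd, config.cell_area_floor
    )

    table = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": [f"c{i:05d}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "area": areas,
        }
    )
    cls = np.asarray(classes)
    for marker in config.marker_names():
        mean = np.full(n, config.background_marker_mean_log)
        sd = np.full(n, config.background_marker_sd_log)
        if marker in config.epithelial_markers:
            sel = cls == "cancer"
            mean[sel] = config.cancer_marker_mean_log
            sd[sel] = config.cancer_marker_sd_log
        if marker == config.pan_immune_marker:
            sel = cls != "cancer"
            mean[sel] = config.pan_immune_mean_log
        for pop in config.immune_populations:
            if pop.name == marker:
                sel = cls == pop.name
                mean[sel] = pop.marker_mean_log
                sd[sel] = pop.marker_sd_log
        table[marker] = rng.lognormal(mean, sd)
    table["cell_class"] = cls
    return table


def generate_cohort(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate a balanced two-group cohort with per-sample metadata.

    Returns ``(tables, meta)`` where ``tables`` maps sample id to its cell
    table and ``meta`` has one row per sample with the group label, an
    on-treatment Ki67 percentage placed unambiguously inside the group's
    classification band (sensitive: uniform on [0.5, 2.7]; resistant:
    uniform on [7.4, 25]) and the matching AQUA score.
    """
    rng = _rng(config, 2**20)  # clinical stream, separate from tissue streams
    tables: dict[str, pd.DataFrame] = {}
    meta_rows = []
    offset = 0
    for group in ("sensitive", "resistant"):
        lo, hi = (0.5, 2.7) if group == "sensitive" else (7.4, 25.0)
        for i in range(config.n_samples_per_group):
            sample_id = f"{group[0].upper()}{i + 1:02d}"
            tables[sample_id] = generate_tissue(config, sample_id, group, offset)
            ki67 = float(rng.uniform(lo, hi))
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "patient_id": f"P{offset + 1:03d}",
                    "timepoint": "onTx",
                    "group": group,
                    "ki67_percent": ki67,
                    "aqua_score": ki67,
                }
            )
            offset += 1
    return tables, pd.DataFrame(meta_rows)


def generate_counts(
    n_segments: int,
    n_genes: int,
    n_neg_probes: int,
    seed: int,
    *,
    expressed_fraction: float = 0.6,
    expressed_mean_log: float = 5.0,
    expressed_sd_log: float = 0.6,
    background_mean_log: float = 0.5,
    background_sd_log: float = 0.3,
    unexpressed_mean_log: float = -0.5,
    segment_scale_sd_log: float = 0.4,
    segment_scales: np.ndarray | None = None,
    neg_probe_constant: float | None = None,
) -> CountMatrix:
    """Generate a segment x gene count matrix with negative probes.

    Expressed genes draw lognormal counts well above the negative-probe
    background; unexpressed genes sit below it (``unexpressed_mean_log``),
    as unexpressed targets do relative to designed background probes, so
    LOQ filtering has a planted expressed/unexpressed ground truth (the
    expressed set is the first ``round(expressed_fraction * n_genes)`` gene
    ids). Per-segment lognormal scale factors make the raw Q3 differ across
    segments; pass ``segment_scales`` of ones to switch that off.
    ``neg_probe_constant`` forces every negative-probe count to one constant,
    a degenerate mode in which the geometric LOQ equals that constant.
    """
    if n_neg_probes < 2:
        raise ValueError("need at least two negative probes")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    segs = [f"AOI{j + 1:03d}" for j in range(n_segments)]
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    probes = [f"NegPrb{i + 1:02d}" for i in range(n_neg_probes)]
    n_expr = int(round(expressed_fraction * n_genes))

    if segment_scales is None:
        scales = rng.lognormal(0.0, segment_scale_sd_log, size=n_segments)
    else:
        scales = np.asarray(segment_scales, dtype=float)
        if scales.shape != (n_segments,) or (scales <= 0).any():
            raise ValueError("segment_scales must be positive, one per segment")

    mean_log = np.full(n_genes + n_neg_probes, background_mean_log)
    sd_log = np.full(n_genes + n_neg_probes, background_sd_log)
    mean_log[n_expr:n_genes] = unexpressed_mean_log
    mean_log[:n_expr] = expressed_mean_log
    sd_log[:n_expr] = expressed_sd_log
    base = rng.lognormal(
        mean_log[:, None], sd_log[:, None], size=(n_genes + n_neg_probes, n_segments)
    )
    counts = pd.DataFrame(base * scales[None, :], index=genes + probes, columns=segs)
    if neg_probe_constant is not None:
        counts.loc[probes] = float(neg_probe_constant)
    labels = {s: ("PanCK+" if j % 2 == 0 else "CD45+") for j, s in enumerate(segs)}
    matrix = CountMatrix(counts=counts, negative_probes=probes, segment_labels=labels)
    matrix.expressed_genes = genes[:n_expr]  # planted ground truth
    return matrix
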