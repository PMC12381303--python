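"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline has a matching generator here:

* :func:`simulate_counts` — multi-patient negative-binomial count matrices
  with planted chromosomal gain/loss segments in tumor populations,
  condition-dependent composition shifts, patient batch effects,
  population expression programs and an optional latent differentiation
  trajectory with gradient genes.
* :func:`simulate_images` — grayscale organoid images as bright disks with
  a controllable degree of budding (surface lobes), plus ground-truth
  masks and mask-derived circularity.
* :func:`simulate_survival` — cohorts whose Weibull event hazard depends
  on a standard-normal signature score through a known log hazard ratio,
  with independent exponential censoring.

The negative binomial uses a shared inverse-dispersion (size) parameter;
its natural zeros supply dropout, so no separate zero-inflation component
is modelled.  Copy-number segments act multiplicatively on the NB mean,
i.e. additively in log space — exactly the signal that windowed smoothing
is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "Population",
    "CNVSegment",
    "TrajectoryDesign",
    "SimulationDesign",
    "GroundTruth",
    "simulate_counts",
    "simulate_cell_table",
    "simulate_images",
    "simulate_survival",
    "design_cnv_benchmark",
    "design_composition_benchmark",
    "design_de_benchmark",
    "design_trajectory_benchmark",
]


@dataclass
class Population:
    """One cell population with per-condition abundance and a program.

    ``program_genes`` maps gene index -> natural-log fold effect applied to
    the NB mean for cells of this population.
    """

    name: str
    is_tumor: bool = False
    proportions: Mapping[str, float] = field(default_factory=dict)
    program_genes: Mapping[int, float] = field(default_factory=dict)


@dataclass
class CNVSegment:
    """Contiguous gene run whose NB mean is multiplied in given populations."""

    chromosome: int
    start_gene_index: int  # index within the chromosome's gene order
    length_genes: int
    multiplier: float
    populations: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValidationError("CNV multiplier must be positive")


@dataclass
class TrajectoryDesign:
    """Latent differentiation axis: ordered populations, gradient genes."""

    populations: Sequence[str]  # ordered from root onward
    gradient_genes: Mapping[int, float] = field(default_factory=dict)

    @property
    def root_population(self) -> str:
        return self.populations[0]


@dataclass
class SimulationDesign:
    n_genes: int = 2000
    n_chromosomes: int = 10
    n_patients: int = 3
    conditions: Sequence[str] = ("UT", "NDexo", "T2Dexo")
    populations: Sequence[Population] = ()
    cnv_segments: Sequence[CNVSegment] = ()
    cells_per_sample: int = 500  # cells per (patient, condition)
    batch_sd: float = 0.0
    size_factor_sd: float = 0.3
    nb_dispersion: float = 2.0
    mean_expression: float = 2.0  # mean counts per gene per cell before effects
    trajectory: TrajectoryDesign | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValidationError("design needs at least one population")
        if self.cells_per_sample <= 0 or self.n_patients <= 0:
            raise ValidationError("degenerate design: zero cells requested")
        if self.batch_sd < 0 or self.nb_dispersion <= 0:
            raise ValidationError("batch_sd must be >= 0 and nb_dispersion > 0")
        names = {p.name for p in self.populations}
        for cond in self.conditions:
            tot = sum(p.proportions.get(cond, 0.0) for p in self.populations)
            if abs(tot - 1.0) > 1e-9:
                raise ValidationError(
                    f"population proportions for condition {cond!r} sum to {tot}, not 1"
                )
        for seg in self.cnv_segments:
            unknown = set(seg.populations) - names
            if unknown:
                raise ValidationError(f"CNV segment targets unknown populations {unknown}")
            if seg.chromosome >= self.n_chromosomes:
                raise ValidationError("CNV segment chromosome out of range")


@dataclass
class GroundTruth:
    """Planted truth aligned one-to-one with the generated entities."""

    cell_table: pd.DataFrame | None = None
    proportions: pd.DataFrame | None = None  # population x condition
    de_genes: pd.DataFrame | None = None  # gene_id, population, log_effect
    segments: pd.DataFrame | None = None
    masks: np.ndarray | None = None  # images x H x W boolean
    circularity: np.ndarray | None = None
    linear_predictor: np.ndarray | None = None


def _gene_annotation(n_genes: int, n_chromosomes: int) -> pd.DataFrame:
    per = int(math.ceil(n_genes / n_chromosomes))
    chroms = np.repeat(np.arange(n_chromosomes), per)[:n_genes]
    within = np.concatenate([np.arange(min(per, n_genes - c * per)) for c in range(n_chromosomes)])
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "symbol": [f"G{i:05d}" for i in range(n_genes)],
            "chromosome": [f"chr{c + 1}" for c in chroms],
            "start_bp": (within + 1) * 1000,
        }
    )


def _segment_gene_indices(design: SimulationDesign, seg: CNVSegment) -> np.ndarray:
    per = int(math.ceil(design.n_genes / design.n_chromosomes))
    start = seg.chromosome * per + seg.start_gene_index
    stop = min(start + seg.length_genes, min((seg.chromosome + 1) * per, design.n_genes))
    return np.arange(start, stop)


def _assign_cells(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    pops = [p.name for p in design.populations]
    rows = []
    for pi in range(design.n_patients):
        patient = f"P{pi + 1}"
        for cond in design.conditions:
            probs = np.array([p.proportions.get(cond, 0.0) for p in design.populations])
            counts = rng.multinomial(design.cells_per_sample, probs)
            for pop, k in zip(pops, counts):
                rows.extend((patient, cond, pop) for _ in range(k))
    table = pd.DataFrame(rows, columns=["patient", "treatment", "population"])
    table.insert(0, "cell_id", [f"C{i:06d}" for i in range(len(table))])
    tumor = {p.name: p.is_tumor for p in design.populations}
    table["is_tumor"] = table["population"].map(tumor)
    return table


def simulate_cell_table(design: SimulationDesign) -> tuple[pd.DataFrame, GroundTruth]:
    """Cell metadata only (no counts) — sufficient for composition analyses."""
    rng = np.random.default_rng(design.seed)
    table = _assign_cells(design, rng)
    props = pd.DataFrame(
        {c: [p.proportions.get(c, 0.0) for p in design.populations] for c in design.conditions},
        index=[p.name for p in design.populations],
    )
    return table, GroundTruth(cell_table=table, proportions=props)


def simulate_counts(design: SimulationDesign) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a gene x cell NB count matrix with all designed effects planted."""
    rng = np.random.default_rng(design.seed)
    cells = _assign_cells(design, rng)
    n_cells = len(cells)
    genes = _gene_annotation(design.n_genes, design.n_chromosomes)

    # baseline gene means (lognormal spread, rescaled to the target mean)
    base = rng.lognormal(0.0, 1.0, design.n_genes)
    base *= design.mean_expression / base.mean()

    log_mean = np.tile(np.log(base)[:, None], (1, n_cells))

    pop_of = cells["population"].to_numpy()
    for pop in design.populations:
        if not pop.program_genes:
            continue
        cols = np.flatnonzero(pop_of == pop.name)
        for g, eff in pop.program_genes.items():
            log_mean[g, cols] += eff

    for seg in design.cnv_segments:
        gidx = _segment_gene_indices(design, seg)
        if gidx.size == 0:
            raise ValidationError("CNV segment lies outside its chromosome")
        cols = np.flatnonzero(np.isin(pop_of, list(seg.populations)))
        log_mean[np.ix_(gidx, cols)] += np.log(seg.multiplier)

    # latent trajectory: ordered populations occupy consecutive time windows
    pseudotime = np.full(n_cells, np.nan)
    if design.trajectory is not None:
        traj = design.trajectory
        order = {name: i for i, name in enumerate(traj.populations)}
        k = len(traj.populations)
        on_path = np.isin(pop_of, list(traj.populations))
        u = rng.uniform(0, 1, n_cells)
        stage = np.array([order.get(p, -1) for p in pop_of], dtype=float)
        pseudotime[on_path] = (stage[on_path] + u[on_path]) / k
        for g, slope in traj.gradient_genes.items():
            log_mean[g, on_path] += slope * (pseudotime[on_path] - 0.5)

    # patient batch effect and per-cell size factors
    batch = rng.normal(0.0, design.batch_sd, design.n_patients)
    patient_idx = cells["patient"].str.slice(1).astype(int).to_numpy() - 1
    log_mean += batch[patient_idx][None, :]
    if design.size_factor_sd > 0:
        log_mean += rng.normal(0.0, design.size_factor_sd, n_cells)[None, :]

    mu = np.exp(log_mean)
    theta = design.nb_dispersion
    lam = rng.gamma(theta, mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    cell_table = cells.copy()
    cell_table["pseudotime"] = pseudotime
    expr = ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_table=genes,
        cell_table=cells[["cell_id", "patient", "treatment", "population"]].assign(
            compartment=np.where(cells["population"].str.startswith("immune"), "immune", "epithelial")
        ),
    )

    de_rows = []
    for pop in design.populations:
        for g, eff in pop.program_genes.items():
            de_rows.append((genes["gene_id"].iat[g], pop.name, eff))
    if design.trajectory is not None:
        for g, slope in design.trajectory.gradient_genes.items():
            de_rows.append((genes["gene_id"].iat[g], "trajectory", slope))
    seg_rows = []
    for seg in design.cnv_segments:
        gidx = _segment_gene_indices(design, seg)
        seg_rows.append(
            (f"chr{seg.chromosome + 1}", gidx[0], gidx[-1], seg.multiplier, ",".join(seg.populations))
        )
    props = pd.DataFrame(
        {c: [p.proportions.get(c, 0.0) for p in design.populations] for c in design.conditions},
        index=[p.name for p in design.populations],
    )
    truth = GroundTruth(
        cell_table=cell_table,
        proportions=props,
        de_genes=pd.DataFrame(de_rows, columns=["gene_id", "population", "log_effect"]),
        segments=pd.DataFrame(
            seg_rows, columns=["chromosome", "first_gene", "last_gene", "multiplier", "populations"]
        ),
    )
    return expr, truth


# --------------------------------------------------------------------------
# organoid images


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def simulate_images(
    n_images: int,
    budding_level: float,
    radius_px: int = 60,
    seed: int = 0,
    noise_sd: float = 10.0,
) -> tuple[np.ndarray, GroundTruth]:
    """8-bit organoid images: a bright disk with ``budding_level``-many lobes.

    ``budding_level`` 0 gives a plain disk (circularity near 1); level 1
    adds many large peripheral lobes, lowering circularity.  The returned
    ground truth carries the binary masks and the circularity of each mask
    computed with the same Crofton perimeter estimator the morphometrics
    stage uses, so the two can be compared like-for-like.
    """
    if radius_px < 10:
        raise ValidationError("radius_px must be >= 10")
    if not (0 <= budding_level <= 1):
        raise ValidationError("budding_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    side = int(radius_px * 4)
    images = np.zeros((n_images, side, side), dtype=np.uint8)
    masks = np.zeros((n_images, side, side), dtype=bool)
    for i in range(n_images):
        cy = side / 2 + rng.uniform(-2, 2)
        cx = side / 2 + rng.uniform(-2, 2)
        mask = _disk_mask((side, side), cy, cx, radius_px)
        n_lobes = int(round(8 * budding_level))
        lobe_r = (0.15 + 0.3 * budding_level) * radius_px
        for _ in range(n_lobes):
            ang = rng.uniform(0, 2 * np.pi)
            ly = cy + radius_px * np.sin(ang)
            lx = cx + radius_px * np.cos(ang)
            mask |= _disk_mask((side, side), ly, lx, lobe_r * rng.uniform(0.7, 1.3))
        img = np.where(mask, 200.0, 30.0)
        img += rng.normal(0.0, noise_sd, (side, side))
        images[i] = np.clip(img, 0, 255).astype(np.uint8)
        masks[i] = mask
    from .morphometrics import mask_circularity  # local import avoids a cycle

    circ = np.array([mask_circularity(m) for m in masks])
    return images, GroundTruth(masks=masks, circularity=circ)


# --------------------------------------------------------------------------
# survival cohorts


def simulate_survival(
    n_subjects: int,
    true_log_hr: float,
    censor_rate: float,
    covariates: Mapping[str, float] | None = None,
    seed: int = 0,
    weibull_shape: float = 1.5,
    baseline_scale: float = 10.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Weibull cohort whose hazard depends on a N(0,1) signature score.

    Event times follow a Weibull proportional-hazards model with linear
    predictor ``true_log_hr * score + sum(beta_j * covariate_j)`` where the
    continuous covariates are independent N(0,1).  Censoring is independent
    exponential with its rate solved numerically so that the expected
    censored fraction equals ``censor_rate``.
    """
    if n_subjects < 50:
        raise ValidationError("n_subjects must be >= 50")
    if not (0 <= censor_rate < 1):
        raise ValidationError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    score = rng.normal(0.0, 1.0, n_subjects)
    lp = true_log_hr * score
    cov_cols: dict[str, np.ndarray] = {}
    for name, beta in (covariates or {}).items():
        x = rng.normal(0.0, 1.0, n_subjects)
        cov_cols[name] = x
        lp = lp + beta * x

    k = weibull_shape
    u = rng.uniform(0, 1, n_subjects)
    # S(t|x) = exp(-(t/scale)^k * e^lp)  =>  t = scale * (-log u / e^lp)^(1/k)
    t_event = baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / k)

    if censor_rate > 0:
        # solve the censoring rate on a fixed unit-exponential sample so the
        # realized censored fraction matches censor_rate deterministically;
        # the censoring stream is seeded as a child sequence so consecutive
        # seeds never share an underlying stream across replicates
        rng_c = np.random.default_rng([seed, 1])
        c_unit = rng_c.exponential(1.0, n_subjects)

        def frac(rate: float) -> float:
            return float(np.mean(c_unit / rate < t_event)) - censor_rate

        lo, hi = 1e-6, 1e6
        rate = scipy.optimize.brentq(frac, lo, hi, xtol=1e-10)
        t_cens = c_unit / rate
    else:
        t_cens = np.full(n_subjects, np.inf)

    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    table = pd.DataFrame({"time": time, "event": event, "score": score, **cov_cols})
    return table, GroundTruth(linear_predictor=lp)


# --------------------------------------------------------------------------
# benchmark designs: the study conditions used by tests and drivers


def design_cnv_benchmark(
    seed: int = 0,
    n_epithelial: int = 500,
    tumor_fraction: float = 0.3,
    n_immune: int = 100,
    n_genes: int = 2000,
    gain_multiplier: float = 2.0,
    gain_length: int = 150,
) -> SimulationDesign:
    """Single-sample tumor/normal CNV calling scenario.

    One patient, one condition: ``tumor_fraction`` of the epithelial cells
    carry a ``gain_length``-gene gain at ``gain_multiplier`` x; immune cells
    serve as the CNV reference.  An immune expression program (50 genes,
    +1.5 natural log) keeps the reference transcriptionally distinct, as in
    real organoid data.
    """
    total = n_epithelial + n_immune
    f_tumor = tumor_fraction * n_epithelial / total
    f_normal = (1 - tumor_fraction) * n_epithelial / total
    f_immune = n_immune / total
    rng = np.random.default_rng(seed + 7)
    immune_program = {int(g): 1.5 for g in rng.choice(n_genes, 50, replace=False)}
    return SimulationDesign(
        n_genes=n_genes,
        n_chromosomes=10,
        n_patients=1,
        conditions=("UT",),
        populations=(
            Population("tumor", True, {"UT": f_tumor}),
            Population("normal", False, {"UT": f_normal}),
            Population("immune", False, {"UT": f_immune}, immune_program),
        ),
        cnv_segments=(CNVSegment(chromosome=2,
                                 start_gene_index=max(0, min(20, math.ceil(n_genes / 10) - gain_length)),
                                 length_genes=gain_length, multiplier=gain_multiplier,
                                 populations=("tumor",)),),
        cells_per_sample=total,
        batch_sd=0.0,
        seed=seed,
    )


def design_composition_benchmark(
    seed: int = 0,
    cells_per_condition: int = 2000,
    n_patients: int = 3,
    expanded_fraction: tuple[float, float] = (0.0136, 0.185),
) -> SimulationDesign:
    """Immune-compartment composition shift scenario.

    A stressed T-cell state occupies 1.36% of the immune compartment under
    the ND-exosome condition and 18.5% under the T2D-exosome condition — a
    13.6-fold designed expansion; remaining immune states absorb the
    complement proportionally.
    """
    f1, f2 = expanded_fraction
    others = {"Tcm": 0.35, "Tem": 0.25, "Teff": 0.25, "MAIT": 0.15}
    pops = [Population("ChopT", False, {"NDexo": f1, "T2Dexo": f2})]
    for name, w in others.items():
        pops.append(
            Population(name, False, {"NDexo": w * (1 - f1), "T2Dexo": w * (1 - f2)})
        )
    return SimulationDesign(
        n_genes=20,
        n_chromosomes=2,
        n_patients=n_patients,
        conditions=("NDexo", "T2Dexo"),
        populations=tuple(pops),
        cells_per_sample=max(1, cells_per_condition // n_patients),
        seed=seed,
    )


def design_de_benchmark(
    seed: int = 0,
    n_genes: int = 2000,
    cells_per_group: int = 250,
    n_patients: int = 3,
    n_program_genes: int = 0,
    log_effect: float = 1.5,
) -> SimulationDesign:
    """Two-condition DE scenario: null by default, or a planted program.

    With ``n_program_genes`` > 0 the first ``n_program_genes`` genes are
    shifted by ``log_effect`` (natural log of the NB mean) in the
    T2D-exosome condition; batch_sd 0.3 plants a patient batch effect the
    hurdle model must absorb.
    """
    rng = np.random.default_rng(seed + 11)
    program = {}
    if n_program_genes:
        genes = rng.choice(n_genes, n_program_genes, replace=False)
        program = {int(g): log_effect for g in genes}
    pops = (
        Population("epi", True, {"NDexo": 1.0, "T2Dexo": 0.0}),
        Population("epi_t2d", True, {"NDexo": 0.0, "T2Dexo": 1.0}, program),
    )
    return SimulationDesign(
        n_genes=n_genes,
        n_chromosomes=5,
        n_patients=n_patients,
        conditions=("NDexo", "T2Dexo"),
        populations=pops,
        cells_per_sample=max(1, cells_per_group // n_patients) * 2,
        batch_sd=0.3,
        seed=seed,
    )


def design_trajectory_benchmark(
    seed: int = 0,
    n_cells: int = 800,
    n_genes: int = 1000,
    n_gradient_genes: int = 200,
    slope: float = 2.0,
) -> SimulationDesign:
    """Differentiation gradient scenario: four ordered states, root first.

    ``n_gradient_genes`` genes ramp up (half) or down (half) linearly in
    the latent time; downstream trajectory inference should recover the
    ordering from the root state onward.
    """
    rng = np.random.default_rng(seed + 13)
    genes = rng.choice(n_genes, n_gradient_genes, replace=False)
    gradient = {int(g): (slope if i % 2 == 0 else -slope) for i, g in enumerate(genes)}
    stages = ("LEC", "LP", "LT_early", "LT_late")
    pops = tuple(Population(s, s.startswith("LT"), {"UT": 0.25}) for s in stages)
    return SimulationDesign(
        n_genes=n_genes,
        n_chromosomes=5,
        n_patients=1,
        conditions=("UT",),
        populations=pops,
        cells_per_sample=n_cells,
        trajectory=TrajectoryDesign(populations=stages, gradient_genes=gradient),
        seed=seed,
    )
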