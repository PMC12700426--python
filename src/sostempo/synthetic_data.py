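"""Synthetic data with the statistical structure of an SOS-induction study.

The generator emulates the experimental design the analysis modules expect:
a circular genome with non-overlapping genes grouped into transcription
units; a repressor operator (dyad box) planted in the promoter of every
SOS gene; negative-binomial count matrices across genotypes (wild type,
repressor deletion, *recA* deletion), treatments and timepoints following a
simple derepression logic; Poisson-background ChIP coverage with Gaussian
read piles over bound promoters; and single-cell reporter trajectories
driven by exponential repressor decay with Hill-type promoter activation,
whose induction time is ordered by intrinsic promoter strength (beta_max).

Ground truth for every simulated object is returned alongside the data so
downstream recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, Gene, revcomp
from .diffexpr import CountMatrix
from .kinetics import CellTrace
from .lexabox import BASES, Pwm, PROMOTER_WINDOW

#: genotype labels used in sample metadata
WT = "WT"
DLEXA = "dlexAdsidA"
DRECA = "drecA"

CONDITIONS = [
    (WT, "none", 0),
    (WT, "MMC", 20),
    (WT, "MMC", 40),
    (DLEXA, "none", 0),
    (DRECA, "none", 0),
    (DRECA, "MMC", 40),
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    Counts: ``basal_mu`` is the mean count of an unexpressed-state gene and
    ``beta_*_range`` the log2 derepression strength (beta_max proxy) drawn
    per SOS transcription unit, early strictly above late so that recovery
    is well-posed.  ``induction_fraction`` gives the fraction of full
    derepression reached at each damage timepoint per temporal class.

    Kinetics: repressor decays as L(t) = L0 exp(-k_c t); promoter activity
    is beta / (1 + (L/K_d)^h); the reporter integrates that activity with
    dilution ``delta``; ``background_au`` is beta-independent cell
    autofluorescence per unit area, against which initial-intensity doubling
    is measured.
    """

    # genome / annotation
    genome_length: int = 300_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (600, 1200)
    intergenic_min: int = 250
    operon_fraction: float = 0.3
    ori_position: int = 0
    # SOS truth
    n_sos_genes: int = 40
    fraction_early: float = 0.55
    beta_early_range: tuple[float, float] = (3.5, 5.0)
    beta_late_range: tuple[float, float] = (2.0, 3.0)
    # counts
    basal_mu: float = 100.0
    dispersion: float = 0.05
    n_replicates: int = 3
    library_factor_sd: float = 0.15
    induction_fraction: dict = field(
        default_factory=lambda: {"early": {20: 0.8, 40: 1.0}, "late": {20: 0.1, 40: 0.7}}
    )
    # planted box
    box_spacer_len: int = 7
    box_halfsite_prob: float = 0.97
    box_offset_range: tuple[int, int] = (-150, -30)
    # coverage
    coverage_background: float = 2.0
    peak_area: float = 2000.0
    peak_sd: float = 40.0
    # kinetics
    L0: float = 100.0
    k_c: float = 0.05
    K_d: float = 10.0
    h: float = 2.0
    delta: float = 0.02
    trace_beta_max: float = 50.0
    background_au: float = 200.0
    trace_noise_cv: float = 0.05
    cell_cv_beta: float = 0.3
    dt: float = 0.1
    t_max: float = 360.0
    obs_interval: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.fraction_early <= 1:
            raise ValueError("fraction_early must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for name in ("L0", "k_c", "K_d", "delta", "trace_noise_cv", "cell_cv_beta",
                     "coverage_background", "peak_area", "peak_sd", "basal_mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.beta_early_range[0] <= self.beta_late_range[1]:
            raise ValueError("early beta range must lie strictly above the late range")
        if self.n_sos_genes > self.n_genes:
            raise ValueError("more SOS genes than genes")
        mean_len = sum(self.gene_length_range) / 2
        if self.genome_length <= self.n_genes * mean_len:
            raise ValueError("genome too short for the requested gene load")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        cfg = cls(**{k: tuple(v) if isinstance(getattr(cls, k, None), tuple) else v
                     for k, v in d.items()})
        cfg.validate()
        return cfg


@dataclass
class SyntheticTruth:
    """Per-gene ground truth: SOS status, temporal class, beta, planted box."""

    genes: pd.DataFrame  # indexed by gene_id

    def __post_init__(self):
        required = {"tu_id", "is_sos", "temporal_class", "beta"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")

    @property
    def sos_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_sos"]])

    @property
    def sos_tus(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["is_sos"], "tu_id"].unique())

    def tu_class(self) -> pd.Series:
        sub = self.genes[self.genes["is_sos"]]
        return sub.groupby("tu_id")["temporal_class"].first()

    def to_json(self, path: str | Path) -> None:
        payload = self.genes.reset_index().to_dict(orient="records")
        Path(path).write_text(json.dumps(payload, indent=1, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        df = pd.DataFrame(json.loads(Path(path).read_text())).set_index("gene_id")
        return cls(df)


def default_box_pwm(config: SimConfig) -> Pwm:
    """Planted-operator model: strong GTTC half-sites around a flat spacer."""
    k = config.box_spacer_len
    p = config.box_halfsite_prob
    cols = []
    for base in "GTTC":
        col = np.full(4, (1 - p) / 3)
        col[BASES.index(base)] = p
        cols.append(col)
    half = np.column_stack(cols)
    spacer = np.full((4, k), 0.25)
    return Pwm(np.hstack([half, spacer, half]), np.full(4, 0.25))


def simulate_annotation(config: SimConfig, rng: np.random.Generator):
    """Pack non-overlapping genes (singletons plus 2-3-gene operons) onto a
    circular genome of random sequence.

    Returns ``(genome, annotation)``; raises if the genes cannot fit.
    """
    config.validate()
    n = config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)

    # TU structure: assign genes to operons of size 2-3 until the operon
    # gene budget is spent, the rest are singletons.
    n_operon_genes = int(round(config.operon_fraction * n))
    sizes: list[int] = []
    remaining = n
    budget = n_operon_genes
    while budget >= 2 and remaining >= 2:
        s = int(rng.integers(2, 4))
        s = min(s, budget, remaining)
        if s < 2:
            break
        sizes.append(s)
        budget -= s
        remaining -= s
    sizes.extend([1] * remaining)
    order = rng.permutation(len(sizes))
    sizes = [sizes[i] for i in order]

    genes: list[Gene] = []
    pos = int(config.intergenic_min)
    gi = 0
    for ti, size in enumerate(sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        tu_id = f"tu{ti + 1:04d}"
        members = []
        for j in range(size):
            glen = int(lengths[gi])
            members.append((pos, pos + glen))
            pos += glen
            if j < size - 1:
                pos += int(rng.integers(5, 31))
            gi += 1
        for start, end in members if strand == "+" else members:
            genes.append(Gene(f"g{len(genes) + 1:04d}", start, end, strand, tu_id))
        pos += int(config.intergenic_min + rng.integers(0, 151))
    if pos > config.genome_length:
        raise ValueError(
            f"genes do not fit: need {pos} bp, genome is {config.genome_length} bp"
        )
    genome = "".join(BASES[i] for i in rng.integers(0, 4, size=config.genome_length))
    ann = Annotation(genes, config.genome_length, ori=config.ori_position)
    return genome, ann


def assign_sos_truth(
    annotation: Annotation, config: SimConfig, rng: np.random.Generator
) -> SyntheticTruth:
    """Select whole TUs as SOS members and draw temporal class and beta.

    Whole TUs are selected (co-transcribed genes share induction), topping up
    with singleton TUs to hit ``n_sos_genes`` exactly; the early fraction is
    applied at the TU level and beta is drawn per TU from its class range.
    """
    tus = annotation.tus()
    tu_ids = list(rng.permutation(sorted(tus)))
    picked: list[str] = []
    count = 0
    for tu in tu_ids:
        size = len(tus[tu])
        if count + size <= config.n_sos_genes:
            picked.append(tu)
            count += size
        if count == config.n_sos_genes:
            break
    if count < config.n_sos_genes:
        raise ValueError("could not select the requested number of SOS genes")
    picked = list(rng.permutation(picked))
    n_early = int(round(config.fraction_early * len(picked)))
    classes = {tu: ("early" if i < n_early else "late") for i, tu in enumerate(picked)}
    betas = {}
    for tu in picked:
        lo, hi = (
            config.beta_early_range if classes[tu] == "early" else config.beta_late_range
        )
        betas[tu] = float(rng.uniform(lo, hi))

    rows = []
    for g in annotation:
        sos = g.tu_id in classes
        rows.append(
            {
                "gene_id": g.gene_id,
                "tu_id": g.tu_id,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "is_sos": sos,
                "temporal_class": classes.get(g.tu_id),
                "beta": betas.get(g.tu_id, 0.0),
                "box_offset": None,
                "box_seq": None,
                "box_center": None,
            }
        )
    return SyntheticTruth(pd.DataFrame(rows).set_index("gene_id"))


def make_null_truth(config: SimConfig) -> SyntheticTruth:
    """Truth table with no SOS genes (global-null count simulations)."""
    rows = [
        {
            "gene_id": f"g{i + 1:04d}",
            "tu_id": f"tu{i + 1:04d}",
            "strand": "+",
            "start": 0,
            "end": 1,
            "is_sos": False,
            "temporal_class": None,
            "beta": 0.0,
        }
        for i in range(config.n_genes)
    ]
    return SyntheticTruth(pd.DataFrame(rows).set_index("gene_id"))


def plant_lexa_boxes(
    annotation: Annotation,
    genome: str,
    truth: SyntheticTruth,
    box_pwm: Pwm,
    rng: np.random.Generator,
    offset_range: tuple[int, int] = (-150, -30),
) -> tuple[str, SyntheticTruth]:
    """Write one operator sampled from ``box_pwm`` into every SOS promoter.

    The box is placed on the coding strand at a strand-aware start offset
    drawn uniformly from ``offset_range`` (relative to the CDS start);
    non-SOS promoters are untouched.  Returns the modified genome and the
    truth with box records filled in.
    """
    L = box_pwm.length
    up, down = PROMOTER_WINDOW
    if L > up + down:
        raise ValueError("box longer than promoter window")
    if offset_range[0] < -up or offset_range[1] + L > down:
        raise ValueError("offset range leaves the promoter window")
    gl = len(genome)
    buf = bytearray(genome.encode())
    genes = truth.genes.copy()
    for gid in genes.index[genes["is_sos"]]:
        g = annotation.get(gid)
        offset = int(rng.integers(offset_range[0], offset_range[1] + 1))
        box = "".join(
            BASES[rng.choice(4, p=box_pwm.probs[:, j])] for j in range(L)
        )
        if g.strand == "+":
            gstart = (g.start + offset) % gl
            written = box
        else:
            gstart = (g.end - offset - L) % gl
            written = revcomp(box)
        for i, ch in enumerate(written):
            buf[(gstart + i) % gl] = ord(ch)
        center = (gstart + L // 2) % gl
        genes.loc[gid, ["box_offset", "box_seq", "box_center"]] = [offset, box, center]
    return bytes(buf).decode(), SyntheticTruth(genes)


def simulate_counts(
    config: SimConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> CountMatrix:
    """NB counts (Var = mu + phi mu^2) for the full genotype/time design.

    Non-SOS genes sit at ``basal_mu`` everywhere.  SOS genes: basal in
    untreated wild type and in the *recA* deletion (damage or not); under
    damage in wild type the mean is basal * (1 + (2^beta - 1) * g(t)) with
    the class-specific induction fraction g(t); in the repressor deletion
    the mean is fully derepressed, basal * 2^beta.
    """
    if config.dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    genes = truth.genes
    n_genes = len(genes)
    beta = genes["beta"].to_numpy(dtype=float)
    is_sos = genes["is_sos"].to_numpy(dtype=bool)
    cls = genes["temporal_class"].astype(object)

    sample_ids, meta_rows, mus = [], [], []
    for genotype, treatment, tp in CONDITIONS:
        mu = np.full(n_genes, config.basal_mu)
        if genotype == WT and treatment == "MMC":
            frac = np.array(
                [
                    config.induction_fraction[c][tp] if s else 0.0
                    for s, c in zip(is_sos, cls)
                ]
            )
            mu = config.basal_mu * (1.0 + (2.0**beta - 1.0) * frac * is_sos)
        elif genotype == DLEXA:
            mu = np.where(is_sos, config.basal_mu * 2.0**beta, config.basal_mu)
        for rep in range(1, config.n_replicates + 1):
            sid = f"{genotype}_{treatment}_{tp}_r{rep}"
            sample_ids.append(sid)
            meta_rows.append(
                {"genotype": genotype, "treatment": treatment,
                 "timepoint_min": tp, "replicate": rep}
            )
            mus.append(mu)

    mu_mat = np.column_stack(mus)
    lib = np.exp(rng.normal(0.0, config.library_factor_sd, size=mu_mat.shape[1]))
    mu_eff = mu_mat * lib[None, :]
    if config.dispersion == 0:
        counts = rng.poisson(mu_eff)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu_eff))
    return CountMatrix(
        pd.DataFrame(counts, index=genes.index, columns=sample_ids),
        pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id")),
    )


def simulate_coverage(
    annotation: Annotation,
    truth: SyntheticTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-bp read counts: Poisson background plus a Gaussian read pile
    (Poisson total ~ ``peak_area``, SD ``peak_sd``) over each planted box."""
    gl = annotation.genome_length
    track = rng.poisson(config.coverage_background, size=gl).astype(float)
    centers = truth.genes.loc[truth.genes["is_sos"], "box_center"].dropna()
    for center in centers:
        n_reads = rng.poisson(config.peak_area)
        pos = np.rint(rng.normal(float(center), config.peak_sd, size=n_reads)).astype(int) % gl
        np.add.at(track, pos, 1.0)
    return track


def simulate_traces(
    config: SimConfig,
    rng: np.random.Generator,
    n_cells: int,
    beta_max: float | None = None,
    cell_prefix: str = "cell",
) -> list[CellTrace]:
    """Single-cell reporter trajectories under exponential repressor decay.

    Per cell, beta ~ lognormal(median beta_max, cell_cv_beta); repression is
    Hill-type in L(t) = L0 exp(-k_c t); the reporter F obeys
    dF/dt = a(t) - delta F integrated by explicit Euler from the pre-damage
    steady state F(0) = a(0)/delta.  Observed area-normalised intensity is
    (F + background_au) with multiplicative Gaussian noise, and the area
    channel is a slowly growing positive series.
    """
    if config.dt > 1.0:
        raise ValueError("integration step dt must be <= 1 min")
    if config.t_max < 60:
        raise ValueError("t_max must be >= 60 min")
    beta0 = config.trace_beta_max if beta_max is None else beta_max
    sigma = np.sqrt(np.log1p(config.cell_cv_beta**2))
    beta_cell = beta0 * np.exp(rng.normal(0.0, sigma, size=n_cells))

    n_steps = int(round(config.t_max / config.dt))
    tgrid = np.arange(n_steps + 1) * config.dt
    L = config.L0 * np.exp(-config.k_c * tgrid)
    with np.errstate(over="ignore"):  # steep Hill coefficients saturate cleanly
        s = (
            1.0 / (1.0 + (L / config.K_d) ** config.h)
            if config.K_d > 0
            else np.ones_like(L)
        )

    if config.delta > 0:
        F = beta_cell * s[0] / config.delta
    else:
        if beta_cell.max() * config.t_max > 1e12:
            raise OverflowError("delta = 0 with unbounded reporter accumulation")
        F = np.zeros(n_cells)

    obs_every = int(round(config.obs_interval / config.dt))
    obs_idx = set(range(0, n_steps + 1, obs_every))
    obs_t, obs_F = [], []
    for j in range(n_steps + 1):
        if j in obs_idx:
            obs_t.append(tgrid[j])
            obs_F.append(F.copy())
        if j < n_steps:
            F = F + config.dt * (beta_cell * s[j] - config.delta * F)
    obs_t = np.array(obs_t)
    obs_F = np.stack(obs_F)  # time x cells

    noise = 1.0 + rng.normal(0.0, config.trace_noise_cv, size=obs_F.shape)
    observed = (obs_F + config.background_au) * noise

    area0 = rng.uniform(1.5, 2.5, size=n_cells)
    growth = 0.004
    jitter = rng.normal(0.0, 0.01, size=obs_F.shape)
    area = area0[None, :] * np.exp(growth * obs_t[:, None] + jitter)

    traces = []
    for c in range(n_cells):
        traces.append(
            CellTrace(
                f"{cell_prefix}{c + 1:04d}",
                obs_t,
                observed[:, c] * area[:, c],
                area[:, c],
            )
        )
    return traces


@dataclass
class SyntheticDataset:
    config: SimConfig
    genome: str
    annotation: Annotation
    truth: SyntheticTruth
    counts: CountMatrix
    coverage: np.ndarray
    traces_strong: list[CellTrace]
    traces_weak: list[CellTrace]


def generate_dataset(
    config: SimConfig, seed: int | None = None, n_cells: int = 100
) -> SyntheticDataset:
    """End-to-end generation with independent per-stage random streams."""
    config.validate()
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    r_ann, r_box, r_cnt, r_cov, r_tr1, r_tr2 = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    genome, ann = simulate_annotation(config, r_ann)
    truth = assign_sos_truth(ann, config, r_ann)
    genome, truth = plant_lexa_boxes(ann, genome, truth, default_box_pwm(config), r_box)
    counts = simulate_counts(config, truth, r_cnt)
    coverage = simulate_coverage(ann, truth, config, r_cov)
    strong = simulate_traces(config, r_tr1, n_cells, beta_max=config.trace_beta_max,
                             cell_prefix="strong")
    weak = simulate_traces(config, r_tr2, n_cells, beta_max=config.trace_beta_max / 2,
                           cell_prefix="weak")
    return SyntheticDataset(config, genome, ann, truth, counts, coverage, strong, weak)
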