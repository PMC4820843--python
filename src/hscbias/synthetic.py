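"""Seeded synthetic data with the statistical structure the analyses assume.

Three generators mirror the study's data modalities:

* ``simulate_counts`` — a two-group (young/old) single-cell count matrix.
  Expression of gene g in cell c is a Bernoulli detection event times a
  negative-binomial count; a designated "platelet program" gene set is
  shifted in the old group both in detection probability (additive
  ``freq_effect``) and conditional expression level (multiplicative
  ``level_effect``), emulating increased frequency and level of
  platelet-specific gene expression in aged HSCs.
* ``simulate_ct`` — a single-cell qPCR Ct matrix with a reference assay,
  per-assay per-group detection probabilities and programmed ΔCt shifts.
* ``simulate_clones`` — single-HSC transplantation clone tables drawn
  around the four lineage-output archetypes (Pl, Pl/My, Ba, Ly) with
  log-normal noise, a planted exact-count subtype composition and a
  fraction of non-engrafting clones.

All generators are deterministic in their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import LINEAGES, CloneRecord, CountsMatrix, CtMatrix, GeneSet


@dataclass
class SimulationConfig:
    """Two-group count-matrix simulation parameters.

    ``baseline_detection`` is the detection probability of program genes in
    both groups at baseline (the platelet program is mostly silent in young
    cells); program genes in the old group get ``freq_effect`` added — the
    sum must stay in [0, 1] — and their negative-binomial mean multiplied
    by a per-gene log-normal factor with median ``level_effect`` and log-sd
    ``level_effect_sd`` (0 makes the fold shift homogeneous).

    Background-gene detection follows ``detection_mode``. The default,
    ``"expression_linked"``, ties dropout to abundance through a logistic
    in log2 mean with slope ``detection_steepness`` (log2 units), rescaled
    into ``detection_range`` — highly expressed genes are rarely missed,
    lowly expressed ones mostly drop out, giving cells the shared
    detection profile real single-cell data show. ``"uniform"`` applies
    ``baseline_detection`` to every gene instead (useful for degenerate
    checks). ``dispersion`` is the negative-binomial alpha
    (var = mu + alpha * mu^2); 0 collapses to Poisson. Per-gene base means
    are log-normal around ``mean_log_expression`` (natural-log scale);
    cells get a relative size factor from ``library_size_range``.
    """

    n_cells_per_group: int = 100
    n_genes: int = 2000
    n_program_genes: int = 50
    program_genes: GeneSet | None = None
    baseline_detection: float = 0.15
    freq_effect: float = 0.75
    level_effect: float = 4.0
    level_effect_sd: float = 0.5
    mean_log_expression: float = 3.0
    gene_mean_sd: float = 2.0
    dispersion: float = 0.5
    detection_mode: str = "expression_linked"
    detection_range: tuple[float, float] = (0.02, 0.98)
    detection_steepness: float = 0.75
    library_size_range: tuple[int, int] = (50_000, 200_000)
    group_labels: tuple[str, str] = ("young", "old")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_detection <= 1.0:
            raise ValueError("baseline_detection must be a probability")
        if not 0.0 <= self.baseline_detection + self.freq_effect <= 1.0:
            raise ValueError("baseline_detection + freq_effect outside [0, 1]")
        if self.level_effect <= 0:
            raise ValueError("level_effect must be positive")
        if self.level_effect_sd < 0:
            raise ValueError("level_effect_sd must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.detection_mode not in ("expression_linked", "uniform"):
            raise ValueError(f"unknown detection_mode {self.detection_mode!r}")
        if not 0.0 <= self.detection_range[0] <= self.detection_range[1] <= 1.0:
            raise ValueError("detection_range must be an increasing pair in [0, 1]")
        if self.program_genes is None:
            if self.n_program_genes > self.n_genes:
                raise ValueError("more program genes than genes")
            self.program_genes = GeneSet(
                name="platelet_program",
                members={f"PROG{i:04d}" for i in range(self.n_program_genes)},
                description="programmed platelet-program genes",
            )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + alpha mu^2 (Poisson at 0)."""
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _base_detection(config: SimulationConfig, base_mean: np.ndarray, is_prog: np.ndarray) -> np.ndarray:
    """Per-gene baseline detection probability (shared by both groups)."""
    if config.detection_mode == "uniform":
        return np.full(base_mean.size, config.baseline_detection)
    from scipy.special import expit

    v = np.log2(base_mean)
    lo, hi = config.detection_range
    p = lo + (hi - lo) * expit((v - np.median(v)) / config.detection_steepness)
    p[is_prog] = config.baseline_detection  # program silent-ish at baseline
    return p


def simulate_counts(config: SimulationConfig) -> tuple[CountsMatrix, pd.DataFrame]:
    """Draw a counts matrix plus a per-gene truth table.

    The truth table records each gene's programmed status and its detection
    probability and mean in each group.
    """
    rng = np.random.default_rng(config.seed)
    n_prog = len(config.program_genes.members)
    gene_ids = sorted(config.program_genes.members) + [
        f"G{i:05d}" for i in range(config.n_genes - n_prog)
    ]
    young, old = config.group_labels
    cell_ids = [f"{young}_{i:03d}" for i in range(config.n_cells_per_group)] + [
        f"{old}_{i:03d}" for i in range(config.n_cells_per_group)
    ]
    groups = {c: (young if c.startswith(young) else old) for c in cell_ids}
    is_prog = np.array([g in config.program_genes.members for g in gene_ids])

    base_mean = rng.lognormal(
        mean=config.mean_log_expression, sigma=config.gene_mean_sd, size=len(gene_ids)
    )
    base_p = _base_detection(config, base_mean, is_prog)
    fold = np.ones(len(gene_ids))
    fold[is_prog] = config.level_effect * np.exp(
        rng.normal(0.0, config.level_effect_sd, n_prog)
    )
    lo, hi = config.library_size_range
    size_factor = rng.integers(lo, hi + 1, size=len(cell_ids)) / ((lo + hi) / 2)

    detect_p = np.repeat(base_p[:, None], len(cell_ids), axis=1)
    mean = base_mean[:, None] * size_factor[None, :]
    old_mask = np.array([groups[c] == old for c in cell_ids])
    detect_p[np.ix_(is_prog, old_mask)] += config.freq_effect
    mean[np.ix_(is_prog, old_mask)] *= fold[is_prog, None]

    detected = rng.random(detect_p.shape) < detect_p
    counts = np.where(detected, _nb_sample(rng, mean, config.dispersion), 0)
    # detection in the analyses means count > 0; ensure a detected draw is nonzero
    counts[detected & (counts == 0)] = 1

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_program": is_prog,
            "detection_p_young": base_p,
            "detection_p_old": np.where(is_prog, base_p + config.freq_effect, base_p),
            "mean_young": base_mean,
            "mean_old": base_mean * fold,
        }
    )
    return CountsMatrix(gene_ids, cell_ids, counts.astype(np.int64), groups), truth


@dataclass
class CtSimulationConfig:
    """Single-cell qPCR simulation parameters.

    ``assays`` maps assay id -> per-group (detection probability, mean ΔCt
    relative to the reference). The reference assay is detected with
    ``reference_detection`` probability; reference Ct is drawn around
    ``reference_ct_mean``; detected assays get
    Ct = Ct_ref - ΔCt + N(0, noise_sd).
    """

    assays: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "Vwf": {"young": (0.4, 2.0), "old": (0.7, 4.0)},
            "Itgb3": {"young": (0.3, 1.0), "old": (0.6, 2.5)},
            "Gata1": {"young": (0.2, 0.5), "old": (0.3, 1.0)},
        }
    )
    n_cells_per_group: int = 150
    reference_assay: str = "Kit"
    reference_detection: float = 0.95
    reference_ct_mean: float = 15.0
    reference_ct_sd: float = 0.5
    noise_sd: float = 0.5
    lod: float = 40.0
    group_labels: tuple[str, str] = ("young", "old")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.reference_detection <= 1.0:
            raise ValueError("reference_detection must be a probability")
        for assay, per_group in self.assays.items():
            for g, (p, _d) in per_group.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{assay}/{g}: detection probability {p}")


def simulate_ct(config: CtSimulationConfig) -> tuple[CtMatrix, pd.DataFrame, dict[str, str]]:
    """Draw a Ct matrix, the per-assay truth table and the cell->group map."""
    rng = np.random.default_rng(config.seed)
    young, old = config.group_labels
    cell_ids = [f"{young}_{i:03d}" for i in range(config.n_cells_per_group)] + [
        f"{old}_{i:03d}" for i in range(config.n_cells_per_group)
    ]
    groups = {c: (young if c.startswith(young) else old) for c in cell_ids}
    assay_ids = [config.reference_assay] + sorted(config.assays)
    ct = np.full((len(assay_ids), len(cell_ids)), np.nan)

    ref_detected = rng.random(len(cell_ids)) < config.reference_detection
    ref_ct = rng.normal(config.reference_ct_mean, config.reference_ct_sd, len(cell_ids))
    ref_ct = np.clip(ref_ct, 1.0, config.lod)
    ct[0, ref_detected] = ref_ct[ref_detected]

    rows = []
    for ai, assay in enumerate(assay_ids[1:], start=1):
        per_group = config.assays[assay]
        for ci, cell in enumerate(cell_ids):
            p, dct = per_group[groups[cell]]
            if rng.random() < p:
                val = ref_ct[ci] - dct + rng.normal(0.0, config.noise_sd)
                ct[ai, ci] = np.clip(val, 1e-6, config.lod)
        rows.append(
            {
                "assay_id": assay,
                "detection_p_young": per_group[young][0],
                "detection_p_old": per_group[old][0],
                "delta_ct_young": per_group[young][1],
                "delta_ct_old": per_group[old][1],
            }
        )
    matrix = CtMatrix(
        assay_ids=assay_ids,
        cell_ids=cell_ids,
        ct=ct,
        reference_assay=config.reference_assay,
        lod=config.lod,
    )
    return matrix, pd.DataFrame(rows), groups


# default archetype profiles: percent contribution (platelet, myeloid, B, T)
_DEFAULT_PROFILES = {
    "Pl": {"platelet": 6.0, "myeloid": 0.5, "B": 0.2, "T": 0.2},
    "Pl/My": {"platelet": 4.0, "myeloid": 4.0, "B": 0.3, "T": 0.3},
    "Ba": {"platelet": 1.5, "myeloid": 1.5, "B": 1.5, "T": 1.5},
    "Ly": {"platelet": 0.1, "myeloid": 0.3, "B": 3.0, "T": 2.0},
}


@dataclass
class CloneSimulationConfig:
    """Clone-table simulation: a planted mixture of HSC output archetypes.

    ``proportions`` must sum to 1 over the engrafting archetypes; the clone
    count per archetype is the rounded expectation (an exact-count planted
    composition), so recovery checks measure classification error rather
    than multinomial sampling noise. Contributions are the archetype profile
    times log-normal noise exp(N(0, noise_sd)) per lineage and week.
    Non-engrafting clones contribute below 0.1% everywhere.
    """

    n_clones: int = 200
    proportions: dict[str, float] = field(
        default_factory=lambda: {"Pl": 0.4, "Pl/My": 0.3, "Ba": 0.2, "Ly": 0.1}
    )
    profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PROFILES.items()}
    )
    noise_sd: float = 0.3
    frac_nonengrafting: float = 0.1
    weeks: tuple[int, ...] = (10, 16)
    group: str = "old"
    source_population: str = "Vwf+"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype proportions sum to {total}, not 1")
        if not 0.0 <= self.frac_nonengrafting < 1.0:
            raise ValueError("frac_nonengrafting must be in [0, 1)")
        missing = [k for k in self.proportions if k not in self.profiles]
        if missing:
            raise ValueError(f"no profile for archetypes: {missing}")


def simulate_clones(
    config: CloneSimulationConfig,
) -> tuple[list[CloneRecord], dict[str, str]]:
    """Draw clone records plus the truth label per clone.

    Truth labels are the archetype names, or ``"none"`` for non-engrafting
    clones.
    """
    rng = np.random.default_rng(config.seed)
    n_none = int(round(config.n_clones * config.frac_nonengrafting))
    n_engraft = config.n_clones - n_none

    labels: list[str] = []
    names = sorted(config.proportions)
    for name in names:
        labels += [name] * int(round(config.proportions[name] * n_engraft))
    while len(labels) < n_engraft:  # rounding remainder -> largest class
        labels.append(max(names, key=lambda k: config.proportions[k]))
    labels = labels[:n_engraft] + ["none"] * n_none
    rng.shuffle(labels)

    clones, truth = [], {}
    for i, label in enumerate(labels):
        clone_id = f"clone_{i:04d}"
        contributions = {}
        for week in config.weeks:
            if label == "none":
                contributions[week] = {
                    l: float(rng.uniform(0.0, 0.05)) for l in LINEAGES
                }
            else:
                profile = config.profiles[label]
                contributions[week] = {
                    l: float(profile[l] * np.exp(rng.normal(0.0, config.noise_sd)))
                    for l in LINEAGES
                }
        clones.append(
            CloneRecord(
                clone_id=clone_id,
                group=config.group,
                source_population=config.source_population,
                contributions=contributions,
            )
        )
        truth[clone_id] = label
    return clones, truth
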