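"""Synthetic pooled-screen generator with known ground truth.

Emulates the selection structure of a genome-scale loss-of-function screen
under a drug challenge: a no-treatment baseline harvested at time zero, a
vehicle (DMSO) control grown without drug, and two drug doses harvested at
two timepoints, all with replicates.  Most genes are neutral; a minority
are essential (their guides deplete everywhere) and a spiked minority are
synthetic-viable (their knockouts gain fitness only under treatment).

Selection is modeled as exponential growth in proportion space: a gene
with fitness effect ``delta`` (log2 units per unit screen time) changes
its guides' expected abundance by a factor ``2**(delta * t)`` relative to
the pool, which is then renormalized.  A ground-truth effect therefore
maps directly onto the log2 fold change the analysis pipeline measures,
up to a small compositional shift.  Sequencing is multinomial at a fixed
per-sample depth, optionally overdispersed by gamma-perturbing the
expected proportions (gamma shape ``1/overdispersion``, mean 1) before
drawing.

Reproducibility: one integer seed; each sample and the library draw get
an independent substream keyed by a stable hash of its name, so adding or
removing samples never perturbs the counts of the others.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import CountMatrix, SgRNALibrary

TRUTH_LABELS = ("neutral", "essential", "synthetic_viable")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated screen.

    Attributes
    ----------
    n_genes, sgrnas_per_gene :
        Library layout; the real library targeted ~18,166 genes with a few
        guides each, desk-scale runs use 1000-2000 genes.
    frac_essential, frac_synthetic_viable :
        Fractions of genes drawn as essential / synthetic-viable.
    essential_effect :
        log2 proportion change per unit time for essential genes, applied
        in every condition (<= 0).
    sv_effect_treated :
        Additional log2 change per unit time for synthetic-viable genes,
        treated conditions only (>= 0).
    baseline_dispersion :
        Log-normal sigma of initial guide abundances (0 = uniform pool).
    overdispersion :
        0 gives plain multinomial sampling; > 0 gamma-perturbs expected
        proportions before the multinomial draw.
    depth :
        Sequencing reads per sample; >= 10x the guide count is recommended
        (a warning is emitted below that).
    timepoints :
        Harvest times of the treated (and vehicle-control) samples, in
        abstract screen-time units; the default (1, 2) stands for the
        mid- and end-point harvests with cumulative drug exposure folded
        into t.
    doses :
        Labels of the treated arms.
    replicates :
        Replicate plates per condition.
    """

    n_genes: int
    sgrnas_per_gene: int = 5
    frac_essential: float = 0.10
    frac_synthetic_viable: float = 0.025
    essential_effect: float = -1.0
    sv_effect_treated: float = 2.0
    baseline_dispersion: float = 0.5
    overdispersion: float = 0.0
    depth: int = 1_000_000
    timepoints: tuple[float, ...] = (1.0, 2.0)
    doses: tuple[str, ...] = ("ATMi60", "ATMi90")
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.sgrnas_per_gene <= 0:
            raise ConfigError("n_genes and sgrnas_per_gene must be positive")
        for name in ("frac_essential", "frac_synthetic_viable"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_essential + self.frac_synthetic_viable > 1.0:
            raise ConfigError(
                "frac_essential + frac_synthetic_viable must not exceed 1"
            )
        if self.essential_effect > 0:
            raise ConfigError("essential_effect must be <= 0")
        if self.sv_effect_treated < 0:
            raise ConfigError("sv_effect_treated must be >= 0")
        if self.baseline_dispersion < 0:
            raise ConfigError("baseline_dispersion must be >= 0")
        if self.overdispersion < 0:
            raise ConfigError("overdispersion must be >= 0")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.replicates <= 0:
            raise ConfigError("replicates must be positive")
        if any(t <= 0 for t in self.timepoints):
            raise ConfigError("timepoints must be positive")
        # tuples survive YAML round-trips as lists
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        object.__setattr__(self, "doses", tuple(str(d) for d in self.doses))
        if self.depth < 10 * self.n_guides:
            warnings.warn(
                f"depth {self.depth} is below the recommended 10x guide count "
                f"({10 * self.n_guides}); guide-level noise will be high",
                stacklevel=2,
            )

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.sgrnas_per_gene

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        d["doses"] = list(self.doses)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass(frozen=True)
class SimTruth:
    """Per-gene ground truth: class label and fitness effects.

    ``table`` is indexed by gene with columns ``label``
    (neutral | essential | synthetic_viable), ``control_effect`` and
    ``treated_effect`` (log2 per unit time).
    """

    table: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def genes_with(self, label: str) -> pd.Index:
        if label not in TRUTH_LABELS:
            raise ConfigError(f"unknown truth label {label!r}")
        return self.table.index[self.table["label"] == label]

    def effect(self, condition: str) -> pd.Series:
        """Per-gene log2 effect per unit time under 'control' or 'treated'."""
        col = "treated_effect" if condition == "treated" else "control_effect"
        return self.table[col]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SimTruth":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


def _substream(seed: int, name: str) -> np.random.Generator:
    # stable across runs and sample-list changes (unlike hash())
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def draw_truth(config: SimConfig) -> SimTruth:
    """Assign gene classes and effects with the seeded generator.

    Exactly ``round(frac * n_genes)`` genes get each non-neutral label,
    chosen by a seeded permutation; deterministic given the seed.
    """
    n_ess = round(config.frac_essential * config.n_genes)
    n_sv = round(config.frac_synthetic_viable * config.n_genes)
    if n_ess + n_sv > config.n_genes:
        raise ConfigError("rounded class counts exceed n_genes")
    genes = gene_names(config.n_genes)
    rng = _substream(config.seed, "truth")
    perm = rng.permutation(config.n_genes)
    labels = np.array(["neutral"] * config.n_genes, dtype=object)
    labels[perm[:n_ess]] = "essential"
    labels[perm[n_ess : n_ess + n_sv]] = "synthetic_viable"
    control = np.where(labels == "essential", config.essential_effect, 0.0)
    treated = control + np.where(
        labels == "synthetic_viable", config.sv_effect_treated, 0.0
    )
    table = pd.DataFrame(
        {"label": labels, "control_effect": control, "treated_effect": treated},
        index=pd.Index(genes, name="gene"),
    )
    return SimTruth(table)


_BASES = np.array(list("ACGT"))


def simulate_library(config: SimConfig) -> SgRNALibrary:
    """Build the guide library with baseline abundances and spacers.

    Guides are named ``<gene>_sg<i>``.  Baseline abundances are drawn
    log-normal(0, ``baseline_dispersion``) and normalized to proportions
    summing to 1 (uniform when the dispersion is 0); they are stored in
    the library table's ``baseline`` column.  Unique random 20-nt spacers
    are attached so read-level quantification can be exercised on
    simulated data.
    """
    genes = np.repeat(gene_names(config.n_genes), config.sgrnas_per_gene)
    guide_ids = [
        f"{g}_sg{i + 1}"
        for g in gene_names(config.n_genes)
        for i in range(config.sgrnas_per_gene)
    ]
    rng = _substream(config.seed, "library")
    if config.baseline_dispersion == 0:
        baseline = np.full(config.n_guides, 1.0 / config.n_guides)
    else:
        raw = rng.lognormal(mean=0.0, sigma=config.baseline_dispersion,
                            size=config.n_guides)
        baseline = raw / raw.sum()
    spacers = _unique_spacers(rng, config.n_guides, length=20)
    table = pd.DataFrame(
        {"gene": genes, "spacer": spacers, "baseline": baseline},
        index=pd.Index(guide_ids, name="guide_id"),
    )
    return SgRNALibrary(table)


def _unique_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def sample_plan(config: SimConfig) -> pd.DataFrame:
    """The sample sheet a run of the screen produces.

    One ``nt`` baseline harvested at t=0 per replicate, vehicle controls
    at every treated timepoint, and each dose x timepoint x replicate.
    """
    rows = []
    for r in range(1, config.replicates + 1):
        rows.append((f"NT-ct_r{r}", "nt", "", 0.0, r))
    for t in config.timepoints:
        for r in range(1, config.replicates + 1):
            rows.append((f"D-ct_t{t:g}_r{r}", "control", "DMSO", t, r))
    for dose in config.doses:
        for t in config.timepoints:
            for r in range(1, config.replicates + 1):
                rows.append((f"{dose}_t{t:g}_r{r}", "treated", dose, t, r))
    df = pd.DataFrame(
        rows, columns=["sample_id", "condition", "dose", "timepoint", "replicate"]
    )
    return df.set_index("sample_id")


def expected_proportions(
    baseline: np.ndarray,
    guide_effects: np.ndarray,
    timepoint: float,
) -> np.ndarray:
    """Renormalized expected guide proportions after selection.

    ``p_i \\propto baseline_i * 2**(effect_i * t)``; with all effects 0 this
    returns the baseline proportions exactly.
    """
    if timepoint == 0 or not np.any(guide_effects):
        return np.asarray(baseline, dtype=float)  # exact neutrality
    logw = np.log2(baseline) + guide_effects * timepoint
    logw -= logw.max()  # overflow guard
    w = np.exp2(logw)
    return w / w.sum()


def simulate_screen(
    config: SimConfig,
) -> tuple[CountMatrix, SgRNALibrary, SimTruth]:
    """Generate the full screen: counts, library and ground truth.

    Each sample's counts are multinomial(depth, p) where p are the
    expected post-selection proportions, gamma-perturbed first when
    ``overdispersion > 0``.  Column sums equal ``depth`` exactly and the
    whole object is bitwise-reproducible from (config, seed).
    """
    truth = draw_truth(config)
    library = simulate_library(config)
    baseline = library.table["baseline"].to_numpy()
    plan = sample_plan(config)

    gene_control = truth.effect("control").reindex(library.genes).to_numpy()
    gene_treated = truth.effect("treated").reindex(library.genes).to_numpy()

    counts = np.empty((config.n_guides, len(plan)), dtype=np.int64)
    for j, (sample_id, row) in enumerate(plan.iterrows()):
        effects = gene_treated if row["condition"] == "treated" else gene_control
        p = expected_proportions(baseline, effects, float(row["timepoint"]))
        rng = _substream(config.seed, f"sample:{sample_id}")
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            w = rng.gamma(shape=shape, scale=1.0 / shape, size=p.size)
            p = p * w
            p = p / p.sum()
        counts[:, j] = rng.multinomial(config.depth, p)

    cm = CountMatrix(
        pd.DataFrame(counts, index=library.guides, columns=plan.index),
        plan.copy(),
    )
    return cm, library, truth
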