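"""Seeded generators for isogenic dosage-series RNA-seq count data.

The generators emulate the structure of a four-line isogenic experiment:
a corrected wildtype (CorrWT, 0 inactivated alleles), a heterozygous line
(Het, 1 allele) and two independent null clones (NullA / NullB, 2 alleles),
each sequenced in triplicate — 12 libraries in total — with ERCC-style
spike-in standards (92 species spanning a 10^6 concentration range, in two
mixes) added to every library.

Endogenous counts are negative-binomial with the edgeR-style
parameterization var = mu + phi * mu^2.  A configurable subset of genes is
"dosage responsive": their log2 expression shifts by ``per_dosage_log2fc``
for every inactivated allele, so Het moves 1x and the Null clones 2x the
per-allele effect.  A second planted class ("nonlinear") is differentially
expressed in every mutant line but with a flat profile, so it should be
picked up by pairwise testing yet rejected by the dosage-linearity rule.
Every simulation emits a ground-truth table for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError

SAMPLES = ("CorrWT", "Het", "NullA", "NullB")
SAMPLE_DOSAGE = {"CorrWT": 0, "Het": 1, "NullA": 2, "NullB": 2}

# ERCC mixes split the species into four subpools with fixed mix1:mix2
# molar ratios (4:1, 1:1, 2:3, 1:2); the default mirrors that layout.
DEFAULT_MIX_RATIO_GROUPS = (
    (0.25, 4.0),
    (0.25, 1.0),
    (0.25, 2.0 / 3.0),
    (0.25, 0.5),
)


@dataclass(frozen=True)
class Library:
    library_id: str
    sample: str
    dosage: int
    replicate: int
    spike_mix: str
    depth: float


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered collection of sequencing libraries with dosage metadata."""

    libraries: tuple[Library, ...]

    def __post_init__(self) -> None:
        ids = [lib.library_id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate library_ids in design")
        for lib in self.libraries:
            if lib.sample not in SAMPLE_DOSAGE:
                raise ValidationError(f"unknown sample {lib.sample!r}")
            if lib.dosage != SAMPLE_DOSAGE[lib.sample]:
                raise ValidationError(
                    f"library {lib.library_id}: dosage {lib.dosage} does not "
                    f"match sample {lib.sample}"
                )

    @property
    def library_ids(self) -> list[str]:
        return [lib.library_id for lib in self.libraries]

    def libraries_for(self, sample: str) -> list[str]:
        return [l.library_id for l in self.libraries if l.sample == sample]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(lib) for lib in self.libraries])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExperimentDesign":
        libs = tuple(
            Library(
                library_id=str(r.library_id),
                sample=str(r.sample),
                dosage=int(r.dosage),
                replicate=int(r.replicate),
                spike_mix=str(r.spike_mix),
                depth=float(r.depth),
            )
            for r in df.itertuples(index=False)
        )
        return cls(libraries=libs)


@dataclass(frozen=True)
class GeneParams:
    """Simulation parameters for one endogenous gene.

    ``per_dosage_log2fc`` is the log2 fold change added per inactivated
    allele; ``nonlinear_profile`` instead fixes the log2 fold change per
    mutant sample (Het, NullA, NullB) directly, for genes that respond but
    not linearly in dosage.
    """

    gene_id: str
    baseline_mean: float
    dispersion: float
    per_dosage_log2fc: float = 0.0
    true_class: str = "null"
    nonlinear_profile: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ParameterError(f"{self.gene_id}: baseline_mean must be > 0")
        if self.dispersion < 0:
            raise ParameterError(f"{self.gene_id}: dispersion must be >= 0")
        ok = {
            "linear_up": self.per_dosage_log2fc > 0 and self.nonlinear_profile is None,
            "linear_down": self.per_dosage_log2fc < 0 and self.nonlinear_profile is None,
            "null": self.per_dosage_log2fc == 0 and self.nonlinear_profile is None,
            "nonlinear": self.nonlinear_profile is not None,
        }.get(self.true_class)
        if not ok:
            raise ValidationError(
                f"{self.gene_id}: true_class {self.true_class!r} inconsistent "
                "with effect parameters"
            )

    def log2fc_for(self, sample: str) -> float:
        """Log2 fold change of this gene in `sample` relative to CorrWT."""
        if self.nonlinear_profile is not None:
            idx = {"CorrWT": None, "Het": 0, "NullA": 1, "NullB": 2}[sample]
            return 0.0 if idx is None else self.nonlinear_profile[idx]
        return self.per_dosage_log2fc * SAMPLE_DOSAGE[sample]


@dataclass(frozen=True)
class SpikeInReference:
    """Nominal concentrations (attomol/uL) of spike species in two mixes."""

    species: pd.DataFrame  # spike_id, length_nt, gc_fraction, conc_mix1, conc_mix2

    def __post_init__(self) -> None:
        required = {"spike_id", "length_nt", "gc_fraction", "conc_mix1", "conc_mix2"}
        missing = required - set(self.species.columns)
        if missing:
            raise ValidationError(f"spike reference missing columns {sorted(missing)}")
        for col in ("conc_mix1", "conc_mix2"):
            if (self.species[col] <= 0).any():
                raise ValidationError(f"non-positive concentration in {col}")
        if self.species["spike_id"].duplicated().any():
            raise ValidationError("duplicate spike_ids")

    @property
    def spike_ids(self) -> list[str]:
        return self.species["spike_id"].tolist()

    def concentrations(self, mix: str) -> pd.Series:
        if mix not in ("mix1", "mix2"):
            raise ParameterError(f"unknown spike mix {mix!r}")
        return self.species.set_index("spike_id")[f"conc_{mix}"]


@dataclass
class CountMatrix:
    """Integer gene x library count matrix with design metadata.

    ``counts`` rows are endogenous genes followed by spike species;
    ``is_spike`` flags the spike rows.
    """

    counts: pd.DataFrame
    is_spike: pd.Series
    design: ExperimentDesign

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene_ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate library_ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        if list(self.counts.columns) != self.design.library_ids:
            raise ValidationError("count columns do not match design library_ids")
        self.is_spike = self.is_spike.reindex(self.counts.index)
        if self.is_spike.isna().any():
            raise ValidationError("is_spike flags do not cover all genes")
        self.is_spike = self.is_spike.astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, library_ids: Sequence[str]) -> "CountMatrix":
        """Restrict to the named libraries (order preserved as given)."""
        missing = [l for l in library_ids if l not in self.counts.columns]
        if missing:
            raise LookupError(f"libraries not in matrix: {missing}")
        by_id = {l.library_id: l for l in self.design.libraries}
        sub_design = ExperimentDesign(
            libraries=tuple(by_id[l] for l in library_ids)
        )
        return CountMatrix(
            counts=self.counts[list(library_ids)].copy(),
            is_spike=self.is_spike.copy(),
            design=sub_design,
        )

    def endogenous(self) -> pd.DataFrame:
        return self.counts.loc[~self.is_spike]

    def spikes(self) -> pd.DataFrame:
        return self.counts.loc[self.is_spike]


def make_default_design(
    seed: int = 0,
    depth_mean: float = 5e5,
    depth_cv: float = 0.1,
) -> ExperimentDesign:
    """Build the canonical 12-library design: 4 sample lines x 3 replicates.

    Per-library expected depths are drawn log-normally around ``depth_mean``
    with coefficient of variation ``depth_cv`` (``depth_cv=0`` gives exactly
    equal depths).  Spike mixes alternate across replicates so both mixes
    appear within every sample line.
    """
    if depth_mean <= 0:
        raise ParameterError("depth_mean must be > 0")
    if depth_cv < 0:
        raise ParameterError("depth_cv must be >= 0")
    rng = np.random.default_rng(seed)
    libs = []
    for sample in SAMPLES:
        for rep in (1, 2, 3):
            if depth_cv == 0:
                depth = float(depth_mean)
            else:
                sigma2 = math.log1p(depth_cv**2)
                mu = math.log(depth_mean) - sigma2 / 2.0
                depth = float(rng.lognormal(mean=mu, sigma=math.sqrt(sigma2)))
            libs.append(
                Library(
                    library_id=f"{sample}_r{rep}",
                    sample=sample,
                    dosage=SAMPLE_DOSAGE[sample],
                    replicate=rep,
                    spike_mix="mix1" if rep % 2 == 1 else "mix2",
                    depth=depth,
                )
            )
    return ExperimentDesign(libraries=tuple(libs))


def make_spike_reference(
    n_species: int = 92,
    dynamic_range: float = 1e6,
    mix_ratio_groups: Sequence[tuple[float, float]] = DEFAULT_MIX_RATIO_GROUPS,
    seed: int = 0,
    length_range: tuple[int, int] = (250, 2000),
    gc_range: tuple[float, float] = (0.3, 0.7),
) -> SpikeInReference:
    """Generate a spike-in reference table.

    Mix-1 concentrations are log-uniformly spaced so that
    max/min == ``dynamic_range`` exactly.  Species are partitioned into
    ratio groups; a species in a group with ratio r has
    conc_mix2 = conc_mix1 / r.  Lengths and GC fractions are drawn uniformly
    from the configured ranges.
    """
    if n_species < 2:
        raise ParameterError("n_species must be >= 2")
    if dynamic_range < 1:
        raise ParameterError("dynamic_range must be >= 1")
    fractions = [f for f, _ in mix_ratio_groups]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("mix_ratio_groups fractions must sum to 1")
    rng = np.random.default_rng(seed)

    conc1 = np.geomspace(1.0, dynamic_range, n_species)
    # group sizes: largest-remainder apportionment so they sum to n_species
    raw = np.array(fractions) * n_species
    sizes = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - sizes))[: n_species - sizes.sum()]:
        sizes[i] += 1
    ratios = np.repeat([r for _, r in mix_ratio_groups], sizes)
    rng.shuffle(ratios)

    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_species)
    gc = rng.uniform(gc_range[0], gc_range[1], size=n_species)
    df = pd.DataFrame(
        {
            "spike_id": [f"SPIKE_{i:03d}" for i in range(1, n_species + 1)],
            "length_nt": lengths,
            "gc_fraction": gc,
            "conc_mix1": conc1,
            "conc_mix2": conc1 / ratios,
        }
    )
    return SpikeInReference(species=df)


def make_gene_params(
    n_genes: int = 10_000,
    n_linear_up: int = 100,
    n_linear_down: int = 100,
    n_nonlinear: int = 200,
    per_dosage_log2fc: float = 1.5,
    dispersion: float = 0.02,
    baseline_log_mean: float = 4.0,
    baseline_log_sd: float = 1.5,
    planted_log_mean: float = 5.5,
    planted_log_sd: float = 0.6,
    seed: int = 0,
) -> list[GeneParams]:
    """Draw per-gene simulation parameters for a planted-effect experiment.

    Baseline means are log-normal (natural-log mean/sd given), covering the
    dynamic range typical of bulk expression.  Linear genes shift by
    ``per_dosage_log2fc`` per allele (up or down); nonlinear decoys get a
    flat profile at the same Null-level magnitude in Het and both Nulls, so
    they are differentially expressed everywhere but show no amplification.

    Planted (linear and decoy) genes draw their baselines from a narrower,
    well-expressed stratum (``planted_log_mean``/``planted_log_sd``): the
    benchmark then measures classification of expressed responders rather
    than the detection limit of the filter.  Set these equal to the global
    baseline parameters to plant across the whole abundance range.
    """
    n_special = n_linear_up + n_linear_down + n_nonlinear
    if n_special > n_genes:
        raise ParameterError("planted classes exceed n_genes")
    rng = np.random.default_rng(seed)
    baselines = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n_genes)
    planted_baselines = rng.lognormal(planted_log_mean, planted_log_sd, size=n_genes)
    classes = (
        ["linear_up"] * n_linear_up
        + ["linear_down"] * n_linear_down
        + ["nonlinear"] * n_nonlinear
        + ["null"] * (n_genes - n_special)
    )
    rng.shuffle(classes)
    genes = []
    for i, cls in enumerate(classes):
        gid = f"GENE_{i + 1:05d}"
        base = float(baselines[i] if cls == "null" else planted_baselines[i])
        if cls == "linear_up":
            g = GeneParams(gid, base, dispersion, per_dosage_log2fc, "linear_up")
        elif cls == "linear_down":
            g = GeneParams(gid, base, dispersion, -per_dosage_log2fc, "linear_down")
        elif cls == "nonlinear":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lvl = sign * per_dosage_log2fc
            g = GeneParams(
                gid, base, dispersion, 0.0, "nonlinear",
                nonlinear_profile=(lvl, lvl, lvl),
            )
        else:
            g = GeneParams(gid, base, dispersion, 0.0, "null")
        genes.append(g)
    return genes


def truth_table(genes: Sequence[GeneParams]) -> pd.DataFrame:
    """Ground-truth table: one row per endogenous gene."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "true_class": [g.true_class for g in genes],
            "per_dosage_log2fc": [g.per_dosage_log2fc for g in genes],
        }
    )


def make_synthetic_ontology(
    gene_ids: Sequence[str],
    n_terms: int = 60,
    mean_genes_per_term: int = 30,
    seed: int = 0,
    planted: dict[str, set[str]] | None = None,
):
    """Generate a random is_a DAG with gene annotations for pipeline tests.

    Terms form a layered DAG under a single root; each term is directly
    annotated with a Poisson-sized random draw of genes.  ``planted`` maps
    extra term ids to exact gene sets (e.g. the simulated dosage-responsive
    genes), letting enrichment recover known signal.  Returns an
    :class:`~dosage_de.go_enrichment.OntologyGraph` (unpropagated).
    """
    import networkx as nx

    from .go_enrichment import OntologyGraph

    if n_terms < 2:
        raise ParameterError("n_terms must be >= 2")
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    dag = nx.DiGraph()
    root = "TERM:0000"
    dag.add_node(root, name="root", namespace="synthetic")
    terms = [root]
    for i in range(1, n_terms):
        t = f"TERM:{i:04d}"
        dag.add_node(t, name=f"synthetic term {i}", namespace="synthetic")
        n_parents = 1 + int(rng.random() < 0.3)
        for p in rng.choice(len(terms), size=min(n_parents, len(terms)), replace=False):
            dag.add_edge(t, terms[int(p)])
        terms.append(t)
    annotations: dict[str, set[str]] = {}
    for t in terms[1:]:
        k = min(len(gene_ids), rng.poisson(mean_genes_per_term))
        if k:
            idx = rng.choice(len(gene_ids), size=k, replace=False)
            annotations[t] = {gene_ids[int(i)] for i in idx}
    for i, (term, genes) in enumerate(sorted((planted or {}).items())):
        dag.add_node(term, name=f"planted term {term}", namespace="synthetic")
        dag.add_edge(term, root)
        annotations[term] = set(genes)
    return OntologyGraph(graph=dag, annotations=annotations)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative-binomial draws with var = mu + phi mu^2 (Poisson when phi=0)."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        m, p = mean[~pois], phi[~pois]
        # gamma-Poisson mixture: shape 1/phi, scale phi*mu
        lam = rng.gamma(shape=1.0 / p, scale=p * m)
        out[~pois] = rng.poisson(lam)
    return out


def simulate_counts(
    design: ExperimentDesign,
    genes: Sequence[GeneParams],
    spikes: SpikeInReference,
    spike_mass_fraction: float = 0.03,
    seed: int = 0,
    spike_dispersion: float = 0.01,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a count matrix and return it with its ground-truth table.

    For library l with dosage d, the endogenous mean of gene g is
    ``depth_l * (1 - spike_mass_fraction) * p_g(l)`` where the relative
    abundance ``p_g(l)`` multiplies the baseline by 2^(per-allele log2FC * d)
    (or the nonlinear profile entry for that sample) and is renormalized to
    sum to 1 within the library.  Spike means are proportional to the
    library's mix concentrations and total ``spike_mass_fraction * depth_l``
    in expectation.
    """
    if not genes:
        raise ParameterError("need at least one gene")
    if not (0 < spike_mass_fraction < 1):
        raise ParameterError("spike_mass_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    base = np.array([g.baseline_mean for g in genes])
    phi = np.array([g.dispersion for g in genes])
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("duplicate gene_ids in gene parameters")

    cols = {}
    for lib in design.libraries:
        lfc = np.array([g.log2fc_for(lib.sample) for g in genes])
        abundance = base * np.exp2(lfc)
        p = abundance / abundance.sum()
        mu_endo = lib.depth * (1.0 - spike_mass_fraction) * p

        conc = spikes.concentrations(lib.spike_mix).to_numpy()
        q = conc / conc.sum()
        mu_spike = lib.depth * spike_mass_fraction * q

        cols[lib.library_id] = np.concatenate(
            [
                _nb_draw(rng, mu_endo, phi),
                _nb_draw(rng, mu_spike, np.full_like(mu_spike, spike_dispersion)),
            ]
        )

    index = pd.Index(gene_ids + spikes.spike_ids, name="gene_id")
    counts = pd.DataFrame(cols, index=index, columns=design.library_ids)
    is_spike = pd.Series(
        [False] * len(gene_ids) + [True] * len(spikes.spike_ids), index=index
    )
    matrix = CountMatrix(counts=counts, is_spike=is_spike, design=design)
    return matrix, truth_table(genes)
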