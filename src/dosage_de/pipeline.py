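"""End-to-end orchestration: simulate -> calibrate -> filter -> test ->
classify -> enrich, as one seeded, reproducible run.

A run is driven by a :class:`RunConfig` (YAML-loadable); every stage
writes its TSV/JSON artifacts into the output directory and contributes
row counts and wall time to the :class:`RunManifest`.  Identical config
and seed reproduce identical manifests.  A stage failure writes a FAILED
marker naming the stage and re-raises as :class:`PipelineError`; partial
outputs are retained.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as dio
from .de_testing import (
    ComparisonResult,
    estimate_dispersions,
    estimate_size_factors,
    test_pairwise,
)
from .dosage_classifier import dosage_report, overlap_degs
from .errors import ParameterError, PipelineError, ValidationError
from .go_enrichment import OntologyGraph, enrich_linear_sets
from .spike_calibration import (
    detection_filter,
    estimate_detection_threshold,
    fit_dose_response,
)
from .synthetic_data import (
    CountMatrix,
    make_default_design,
    make_gene_params,
    make_spike_reference,
    make_synthetic_ontology,
    simulate_counts,
)

__version__ = "0.1.0"

COMPARISONS = {
    "HetVsWT": ("Het", "CorrWT"),
    "NullAVsWT": ("NullA", "CorrWT"),
    "NullBVsWT": ("NullB", "CorrWT"),
}


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults mirror the study design."""

    seed: int = 0
    mode: str = "simulate"  # or "from_counts"

    # design / simulation
    depth_mean: float = 5e5
    depth_cv: float = 0.1
    n_genes: int = 10_000
    n_linear_up: int = 100
    n_linear_down: int = 100
    n_nonlinear: int = 200
    per_dosage_log2fc: float = 1.5
    dispersion: float = 0.02
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    n_spike_species: int = 92
    spike_dynamic_range: float = 1e6
    spike_mass_fraction: float = 0.03
    spike_dispersion: float = 0.01

    # thresholds (pipeline decision rules)
    detection_threshold: float = 5.0
    alpha: float = 0.05
    het_fc_min: float = 2.0
    amplification_min: float = 1.5
    node_size: int = 10

    # modelling choices
    norm_method: str = "median_of_ratios"
    test: str = "qlf"
    dispersion_kind: str = "trended"
    pseudocount: float = 0.5
    enrichment_mode: str = "classic"

    # from_counts inputs
    counts_path: str | None = None
    metadata_path: str | None = None
    spike_reference_path: str | None = None
    obo_path: str | None = None
    annotation_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "from_counts"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        for name in ("detection_threshold", "alpha", "het_fc_min",
                     "amplification_min", "node_size"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        planted = self.n_linear_up + self.n_linear_down + self.n_nonlinear
        if self.mode == "simulate" and planted > self.n_genes:
            raise ParameterError("planted gene classes exceed n_genes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Config echo, per-stage counts and wall times for one run."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, **counts) -> None:
        self.stages[stage] = dict(counts)
        self.timings[stage] = round(seconds, 3)

    def validate(self) -> None:
        de = self.stages.get("de", {})
        cls_ = self.stages.get("classify", {})
        if de and cls_:
            sig = [v for k, v in de.items() if k.startswith("significant_")]
            n_overlap = cls_["n_overlap"]
            if cls_["n_linear_up"] + cls_["n_linear_down"] > n_overlap:
                raise ValidationError("linear calls exceed overlap size")
            if sig and n_overlap > min(sig):
                raise ValidationError("overlap exceeds a comparison's significant count")

    def write(self, path: str | Path) -> None:
        """Write the deterministic manifest; wall times go in a sidecar
        timings.json so reruns with the same config+seed are byte-identical."""
        dio.write_json(
            {"config": self.config, "version": self.version, "stages": self.stages},
            path,
        )
        dio.write_json(self.timings, Path(path).with_name("timings.json"))


def validate_counts_file(
    path: str | Path,
    metadata_path: str | Path,
    spike_reference_path: str | Path | None = None,
) -> CountMatrix:
    """Parse and validate a counts file (TSV or MTX) against its metadata.

    Spike rows are identified by id against the spike reference when one
    is given.  Duplicated ids, negative or non-integer entries and
    metadata/matrix library mismatches raise with coordinates.
    """
    design = dio.read_design_tsv(metadata_path)
    spike_ids: frozenset[str] = frozenset()
    if spike_reference_path is not None:
        spike_ids = frozenset(
            dio.read_spike_reference_tsv(spike_reference_path).spike_ids
        )
    return dio.read_counts(path, design, spike_ids)


class _StageTimer:
    def __init__(self, manifest: RunManifest, out_dir: Path):
        self.manifest = manifest
        self.out_dir = out_dir
        self.stage = ""

    def run(self, stage: str, fn, **counts_fn):
        self.stage = stage
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            (self.out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        self.manifest.record(stage, time.perf_counter() - t0, **counts_fn.get("counts", lambda r: {})(result))
        return result


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute all stages in order, writing artifacts and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    timer = _StageTimer(manifest, out)

    # --- stage: counts (simulate or load) ----------------------------------
    def _counts():
        if config.mode == "simulate":
            design = make_default_design(config.seed, config.depth_mean, config.depth_cv)
            spikes = make_spike_reference(
                config.n_spike_species, config.spike_dynamic_range,
                seed=config.seed + 1,
            )
            genes = make_gene_params(
                n_genes=config.n_genes,
                n_linear_up=config.n_linear_up,
                n_linear_down=config.n_linear_down,
                n_nonlinear=config.n_nonlinear,
                per_dosage_log2fc=config.per_dosage_log2fc,
                dispersion=config.dispersion,
                baseline_log_mean=config.baseline_log_mean,
                baseline_log_sd=config.baseline_log_sd,
                seed=config.seed + 2,
            )
            matrix, truth = simulate_counts(
                design, genes, spikes,
                spike_mass_fraction=config.spike_mass_fraction,
                seed=config.seed + 3,
                spike_dispersion=config.spike_dispersion,
            )
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        else:
            if not (config.counts_path and config.metadata_path):
                raise ParameterError("from_counts mode needs counts_path and metadata_path")
            matrix = validate_counts_file(
                config.counts_path, config.metadata_path, config.spike_reference_path
            )
            spikes = (
                dio.read_spike_reference_tsv(config.spike_reference_path)
                if config.spike_reference_path
                else None
            )
            truth = None
        dio.write_counts_tsv(matrix, out / "counts.tsv")
        dio.write_design_tsv(matrix.design, out / "metadata.tsv")
        if spikes is not None:
            dio.write_spike_reference_tsv(spikes, out / "spike_reference.tsv")
        return matrix, spikes, truth

    matrix, spikes, truth = timer.run(
        "counts", _counts,
        counts=lambda r: {
            "n_genes": int((~r[0].is_spike).sum()),
            "n_spikes": int(r[0].is_spike.sum()),
            "n_libraries": len(r[0].library_ids),
        },
    )

    # --- stage: calibrate ---------------------------------------------------
    def _calibrate():
        if spikes is None:
            return None
        fit = fit_dose_response(matrix, spikes, config.detection_threshold)
        est = estimate_detection_threshold(matrix, spikes)
        fit.per_species_table.to_csv(out / "dose_response.tsv", sep="\t", index=False)
        dio.write_json(
            {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "detection_threshold": config.detection_threshold,
                "estimated_threshold": est,
            },
            out / "dose_response.json",
        )
        return fit

    fit = timer.run(
        "calibrate", _calibrate,
        counts=lambda r: {} if r is None else {"r_squared": round(r.r_squared, 4)},
    )

    # --- stage: filter + de -------------------------------------------------
    def _de():
        results: dict[str, ComparisonResult] = {}
        analyzable: dict[str, frozenset[str]] = {}
        for cid, (mut, wt) in COMPARISONS.items():
            mut_libs = matrix.design.libraries_for(mut)
            wt_libs = matrix.design.libraries_for(wt)
            sub = matrix.subset(mut_libs + wt_libs)
            filt = detection_filter(
                sub, mut_libs + wt_libs, config.detection_threshold, comparison_id=cid
            )
            analyzable[cid] = filt.analyzable_genes
            norm = estimate_size_factors(sub, config.norm_method)
            groups = {l: mut for l in mut_libs} | {l: wt for l in wt_libs}
            disp = estimate_dispersions(
                sub, groups, norm, gene_ids=sorted(filt.analyzable_genes)
            )
            res = test_pairwise(
                sub, mut_libs, wt_libs, norm, disp, filt,
                alpha=config.alpha, test=config.test,
                pseudocount=config.pseudocount,
                dispersion_kind=config.dispersion_kind,
                comparison_id=cid,
            )
            dio.write_comparison_tsv(res, out / f"de_{cid}.tsv")
            results[cid] = res
        return results, analyzable

    de_results, analyzable = timer.run(
        "de", lambda: _de(),
        counts=lambda r: {
            **{f"analyzable_{c}": len(g) for c, g in r[1].items()},
            **{f"significant_{c}": len(res.significant_genes) for c, res in r[0].items()},
        },
    )

    # --- stage: classify ----------------------------------------------------
    def _classify():
        overlap = overlap_degs(list(de_results.values()))
        calls = dosage_report(overlap, config.het_fc_min, config.amplification_min)
        calls.table.to_csv(out / "dosage_calls.tsv", sep="\t", index=False)
        dio.write_json(
            {
                "n_overlap": overlap.n_overlap,
                "n_linear_up": calls.n_linear_up,
                "n_linear_down": calls.n_linear_down,
            },
            out / "dosage_summary.json",
        )
        return overlap, calls

    overlap, calls = timer.run(
        "classify", _classify,
        counts=lambda r: {
            "n_overlap": r[0].n_overlap,
            "n_linear_up": r[1].n_linear_up,
            "n_linear_down": r[1].n_linear_down,
        },
    )

    # --- stage: enrich ------------------------------------------------------
    def _enrich():
        background = frozenset().union(*analyzable.values())
        if config.mode == "simulate":
            planted = {}
            if truth is not None:
                up = set(truth.loc[truth.true_class == "linear_up", "gene_id"])
                down = set(truth.loc[truth.true_class == "linear_down", "gene_id"])
                planted = {
                    "TERM:UP": up & background,
                    "TERM:DOWN": down & background,
                }
            graph = make_synthetic_ontology(
                sorted(background), seed=config.seed + 4, planted=planted
            )
        elif config.obo_path and config.annotation_path:
            import pandas as pd

            ann = pd.read_csv(config.annotation_path, sep="\t")
            graph = OntologyGraph.from_obo(config.obo_path, ann)
        else:
            return None
        res_up, res_down = enrich_linear_sets(
            calls, set(background), graph,
            node_size_floor=config.node_size, mode=config.enrichment_mode,
        )
        res_up.table.to_csv(out / "enrichment_linear_up.tsv", sep="\t", index=False)
        res_down.table.to_csv(out / "enrichment_linear_down.tsv", sep="\t", index=False)
        return res_up, res_down, len(background)

    enrich = timer.run(
        "enrich", _enrich,
        counts=lambda r: {} if r is None else {
            "terms_tested_up": len(r[0].table),
            "terms_tested_down": len(r[1].table),
            "background_size": r[2],
        },
    )

    manifest.validate()
    manifest.write(out / "manifest.json")
    return manifest
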