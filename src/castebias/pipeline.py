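"""End-to-end orchestration: sexing -> expression arm -> proteomics arm
-> reports, with a content-hashed artifact manifest.

Every stage writes its tables under the configured output directory and
registers them in the manifest; identical configuration and seed yield
identical hashes. Randomness enters only through the configured seed —
nothing reads the wall clock.
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    tomllib = None

from . import io as cio
from .discriminant import CorrelationPruner, LinearDiscriminant, loocv
from .errors import ConfigurationError, PipelineError, SingularCovarianceError
from .multiplicity import apply_cutoff, corrected_cutoff
from .proteomics import decoy_fdr, differential_abundance, normalize, presence_filter
from .qpcr import analysis_matrices
from .reporting import (
    five_number_summary,
    heatmap_frame,
    ld_histogram_frame,
    maybe_render_figures,
)
from .sexing import filter_females
from .simulate import (
    ExpressionSimConfig,
    GenotypeSimConfig,
    SpectralSimConfig,
    simulate_expression_study,
    simulate_genotype_table,
    simulate_spectral_study,
)
from .stats import results_to_frame, run_per_feature_tests

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration. With no input paths, each arm runs on a
    freshly simulated study at the configured seed."""

    outdir: str = "castebias_out"
    seed: int = 0
    alpha_genes: float = 0.05
    alpha_peptides: float = 0.05
    n_iterations: int = 1000
    correction_method: str = "label_permutation"
    which_p: str = "both"
    prune_r_threshold: float = 0.9
    prune_override: list[str] = field(default_factory=list)
    ridge_lambda: float = 0.0
    priors: str = "empirical"
    min_het_loci: int = 1
    filter_min_count: int = 3
    filter_min_replicates: int = 3
    control_gene_id: str = "RSP8"
    expression_path: str | None = None
    expression_groups_path: str | None = None
    spectral_path: str | None = None
    spectral_groups_path: str | None = None
    spectral_spikein_path: str | None = None
    spectral_mode: str = "in_gel"
    genotypes_path: str | None = None
    render_figures: bool = False

    def validate(self) -> None:
        for name in ("alpha_genes", "alpha_peptides"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ConfigurationError(f"{name}={a} must be in (0, 1)")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.which_p not in ("mwu", "anova", "both"):
            raise ConfigurationError(f"unknown which_p {self.which_p!r}")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an explicit integer")
        for name in (
            "expression_path",
            "expression_groups_path",
            "spectral_path",
            "spectral_groups_path",
            "spectral_spikein_path",
            "genotypes_path",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} does not resolve: {p}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        if tomllib is None:  # pragma: no cover
            raise ConfigurationError("TOML configs need Python >= 3.11")
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the artifact manifest
    (path -> sha256) plus the in-memory result bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    bundle: dict = {}

    def save(frame: pd.DataFrame, name: str) -> Path:
        p = outdir / name
        frame.to_csv(p, sep="\t", index=False, na_rep="")
        artifacts.append(p)
        return p

    # --- sexing arm ---------------------------------------------------
    try:
        if config.genotypes_path:
            gtable = cio.read_genotype_table(config.genotypes_path)
        else:
            gtable = simulate_genotype_table(GenotypeSimConfig(seed=config.seed))
        females, exclusion_log = filter_females(gtable, min_het_loci=config.min_het_loci)
        save(exclusion_log, "exclusion_log.tsv")
        save(pd.DataFrame({"specimen_id": females}), "females.tsv")
        bundle["females"] = females
        bundle["exclusion_log"] = exclusion_log
    except Exception as exc:
        raise PipelineError("sexing", str(exc)) from exc

    # --- expression arm -----------------------------------------------
    try:
        if config.expression_path:
            study = cio.read_expression_study(
                config.expression_path,
                config.expression_groups_path,
                control_gene_id=config.control_gene_id,
            )
        else:
            study = simulate_expression_study(ExpressionSimConfig(seed=config.seed))
        imputed, unimputed, trace = analysis_matrices(study)
        results, untestable = run_per_feature_tests(
            imputed, study.groups, matrix_unimputed=unimputed
        )
        correction = corrected_cutoff(
            imputed,
            study.groups,
            test="mwu",
            alpha=config.alpha_genes,
            n_iterations=config.n_iterations,
            method=config.correction_method,  # type: ignore[arg-type]
            seed=config.seed,
        )
        apply_cutoff(results, correction, which_p=config.which_p)  # type: ignore[arg-type]
        gene_results = results_to_frame(results)
        save(gene_results, "gene_tests.tsv")
        save(correction.report_frame(), "gene_correction.tsv")
        if untestable:
            save(
                pd.DataFrame(untestable, columns=["feature_id", "untestable_reason"]),
                "gene_untestable.tsv",
            )
        bundle["gene_results"] = gene_results
        bundle["gene_correction"] = correction
        bundle["expression_imputed"] = imputed
        bundle["expression_groups"] = study.groups
    except Exception as exc:
        raise PipelineError("expression", str(exc)) from exc

    # --- discriminant -------------------------------------------------
    try:
        sig = gene_results.loc[gene_results["significant"].fillna(False).astype(bool), "feature_id"]
        sig_matrix = imputed.loc[[g for g in imputed.index if str(g) in set(sig)]]
        discriminant_ran = len(sig_matrix) >= 2
        if discriminant_ran:
            pruner = CorrelationPruner(
                r_threshold=config.prune_r_threshold,
                drop_override=config.prune_override or None,
            ).fit(sig_matrix.T)
            retained = sig_matrix.loc[pruner.retained_features_]
            drop_log = pd.DataFrame(
                pruner.drop_log_, columns=["feature_id", "reason", "partner", "r"]
            )
            save(drop_log, "lda_drop_log.tsv")
            lda = LinearDiscriminant(
                ridge_lambda=config.ridge_lambda, priors=config.priors  # type: ignore[arg-type]
            )
            try:
                model = LinearDiscriminant(
                    ridge_lambda=config.ridge_lambda, priors=config.priors  # type: ignore[arg-type]
                ).fit(retained.T, study.groups.to_numpy())
                predicted, accuracy, _ = loocv(retained, study.groups, lda=lda)
            except SingularCovarianceError:
                raise
            save(
                pd.DataFrame(
                    {"feature_id": pruner.retained_features_, "weight": model.weights_}
                ),
                "lda_weights.tsv",
            )
            ld_scores = pd.Series(model.ld_scores_, index=retained.columns, name="ld")
            predictions = pd.DataFrame(
                {
                    "sample_id": retained.columns,
                    "true_group": study.groups.reindex(retained.columns).to_numpy(),
                    "predicted_group": predicted.reindex(retained.columns).to_numpy(),
                    "ld_score": ld_scores.to_numpy(),
                }
            )
            save(predictions, "lda_predictions.tsv")
            bundle["loocv_accuracy"] = accuracy
            bundle["lda_model"] = model
            bundle["ld_scores"] = ld_scores
            save(
                ld_histogram_frame(ld_scores, study.groups), "ld_histogram.tsv"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("discriminant", str(exc)) from exc

    # --- proteomics arm -----------------------------------------------
    try:
        if config.spectral_path:
            stable = cio.read_spectral_table(
                config.spectral_path,
                config.spectral_groups_path,
                mode=config.spectral_mode,
                spikein_path=config.spectral_spikein_path,
            )
        else:
            stable = simulate_spectral_study(SpectralSimConfig(seed=config.seed))
        retained, filter_log = presence_filter(
            stable,
            min_count=config.filter_min_count,
            min_replicates=config.filter_min_replicates,
            group_size=None,
        )
        save(filter_log, "peptide_filter_log.tsv")
        accepted_targets = [h for h in retained if not stable.decoy.get(h, False)]
        fdr = decoy_fdr(stable.decoy, retained) if retained else float("nan")
        normalized = normalize(stable)
        pep_results, pep_correction = differential_abundance(
            normalized,
            stable.groups,
            alpha=config.alpha_peptides,
            n_iterations=config.n_iterations,
            seed=config.seed,
            hit_ids=accepted_targets,
            protein_group=stable.protein_group,
        )
        pep_frame = results_to_frame(pep_results)
        if pep_results and hasattr(pep_results[0], "protein_group"):
            pep_frame["protein_group"] = [r.protein_group for r in pep_results]
        save(pep_frame, "peptide_tests.tsv")
        if pep_correction is not None:
            save(pep_correction.report_frame(), "peptide_correction.tsv")
        bundle["peptide_results"] = pep_frame
        bundle["peptide_correction"] = pep_correction
        bundle["decoy_fdr"] = fdr
        bundle["peptide_normalized"] = normalized.matrix
        bundle["peptide_groups"] = stable.groups

        sig_hits = pep_frame.loc[
            pep_frame["significant"].fillna(False).astype(bool), "feature_id"
        ]
        summaries = []
        for h in sig_hits:
            for g in sorted(stable.groups.unique()):
                cols = stable.groups.index[stable.groups == g]
                s = five_number_summary(normalized.matrix.loc[h, cols])
                summaries.append(
                    {
                        "hit_id": h,
                        "group": g,
                        **{k: v for k, v in s.items() if k != "outliers"},
                        "outliers": ";".join(f"{x:.6g}" for x in s["outliers"]),
                    }
                )
        save(
            pd.DataFrame(
                summaries,
                columns=[
                    "hit_id",
                    "group",
                    "min",
                    "q1",
                    "median",
                    "q3",
                    "max",
                    "whisker_low",
                    "whisker_high",
                    "outliers",
                ],
            ),
            "peptide_summaries.tsv",
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("proteomics", str(exc)) from exc

    # --- reports ------------------------------------------------------
    try:
        heat, flat_flags = heatmap_frame(sig_matrix, study.groups, gene_results)
        hp = outdir / "heatmap_genes.tsv"
        heat.index.name = "feature_id"
        heat.to_csv(hp, sep="\t", na_rep="")
        artifacts.append(hp)
        if config.render_figures:
            ld_frame = (
                ld_histogram_frame(bundle["ld_scores"], study.groups)
                if "ld_scores" in bundle
                else pd.DataFrame()
            )
            artifacts.extend(maybe_render_figures(outdir, heat, ld_frame))
    except Exception as exc:
        raise PipelineError("reports", str(exc)) from exc

    manifest = pd.DataFrame(
        {
            "path": [str(p.relative_to(outdir)) for p in artifacts],
            "sha256": [_sha256(p) for p in artifacts],
        }
    ).sort_values("path", ignore_index=True)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    bundle["manifest"] = manifest
    return bundle
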