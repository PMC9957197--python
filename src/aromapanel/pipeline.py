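"""End-to-end marker-discovery pipeline.

Wires the stages together: OAV screen → pairwise OPLS-DA with diagnostics →
univariate filters → SUS plots → marker panel → multi-class PLS-DA origin
classifier.  Everything downstream of the input table is deterministic given
the configured seed.
"""

from __future__ import annotations

import dataclasses
import datetime
import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np

from .classify import ClassifierModel, ConfusionMatrix, evaluate, fit_classifier
from .data import CompoundMeta, FeatureTable, PipelineConfig, summarize_by_region
from .diagnostics import (JackknifeCI, PermutationResult, SPlotRow, SUSRow,
                          jackknife_ci, permutation_test, s_plot, sus_plot,
                          vip_scores)
from .latent import (CVResult, LatentModel, cross_validate, encode_classes,
                     fit_opls, model_summary)
from .markers import (MarkerDecision, PanelResult, UnivariateRow,
                      assemble_panel, select_pair_candidates,
                      univariate_screen)
from .preprocess import scale_matrix
from .quantify import oav_records, oav_table, primary_aroma_screen

logger = logging.getLogger(__name__)

__all__ = ["PairAnalysis", "RunReport", "analyze_pair", "run_pipeline"]

_OPLS_SPEC = {"kind": "opls_da", "n_pred": 1, "n_orth": 1}


@dataclass
class PairAnalysis:
    """All artifacts of one pairwise OPLS-DA contrast."""

    pair: tuple[str, str]
    model: LatentModel
    cv: CVResult
    summary: dict
    splot: list[SPlotRow]
    vip: list[tuple[str, float]]
    jackknife: list[JackknifeCI]
    permutation: PermutationResult | None
    univariate: list[UnivariateRow]
    decisions: list[MarkerDecision]

    @property
    def candidates(self) -> set[str]:
        return {d.compound for d in self.decisions if d.candidate}


@dataclass
class RunReport:
    """Full record of one pipeline run (reproducible given inputs + seed)."""

    config: PipelineConfig
    oav: dict
    oav_primary: set[str]
    pairs: dict[tuple[str, str], PairAnalysis]
    sus: dict[str, list[SUSRow]]
    panel: PanelResult
    classifier: ClassifierModel | None
    confusion_training: ConfusionMatrix | None
    timestamp: str = ""

    def to_dict(self) -> dict:
        """JSON-serializable report (numeric sections depend only on inputs
        and seed, never on the timestamp)."""
        def _pairkey(p):
            return f"{p[0]}:{p[1]}"

        out = {
            "config": self.config.to_dict(),
            "oav": self.oav,
            "oav_primary": sorted(self.oav_primary),
            "pairs": {},
            "sus": {
                ref: [dataclasses.asdict(r) for r in rows]
                for ref, rows in self.sus.items()
            },
            "panel": {
                "per_pair_candidates": {
                    _pairkey(p): sorted(c)
                    for p, c in self.panel.per_pair_candidates.items()
                },
                "chemometric_union": sorted(self.panel.chemometric_union),
                "final_panel": sorted(self.panel.final_panel),
            },
            "timestamp": self.timestamp,
        }
        for pair, pa in self.pairs.items():
            perm = None
            if pa.permutation is not None:
                perm = {
                    "r2_intercept": pa.permutation.r2_intercept,
                    "q2_intercept": pa.permutation.q2_intercept,
                    "n_permutations": pa.permutation.n_permutations,
                    "valid": pa.permutation.valid,
                    "rows": pa.permutation.rows,
                }
            out["pairs"][_pairkey(pair)] = {
                "summary": pa.summary,
                "splot": [dataclasses.asdict(r) for r in pa.splot],
                "vip": {name: v for name, v in pa.vip},
                "jackknife": [dataclasses.asdict(r) for r in pa.jackknife],
                "permutation": perm,
                "univariate": [dataclasses.asdict(r) for r in pa.univariate],
                "candidates": sorted(pa.candidates),
            }
        if self.classifier is not None:
            out["classifier"] = {
                "summary": self.classifier.training_summary,
                "class_order": self.classifier.class_order,
                "panel_compounds": self.classifier.compound_names,
                "confusion": self.confusion_training.counts.tolist(),
                "accuracy": self.confusion_training.accuracy,
            }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def analyze_pair(
    table: FeatureTable,
    pair: tuple[str, str],
    config: PipelineConfig,
    run_permutation: bool = True,
) -> PairAnalysis:
    """Fit and diagnose one pairwise OPLS-DA contrast."""
    sub = table.subset_regions(pair)
    scaled = scale_matrix(sub.values, mode=config.scaling_mode)
    coding = encode_classes(sub.region_labels)
    model = fit_opls(scaled, coding, n_pred=1, n_orth=1)
    cv = cross_validate(_OPLS_SPEC, sub.values, sub.region_labels,
                        folds=config.cv_folds, seed=config.seed,
                        scaling=config.scaling_mode)
    splot = s_plot(model, scaled, sub.compound_names,
                   cov_threshold=config.splot_cov_threshold,
                   corr_threshold=config.splot_corr_threshold)
    vip = vip_scores(model, sub.compound_names)
    jk = jackknife_ci(cv, sub.compound_names, alpha=config.alpha_ci,
                      reference_loading=model.loadings_pred[:, 0])
    perm = None
    if run_permutation:
        perm = permutation_test(sub.values, sub.region_labels,
                                n_perm=config.n_permutations,
                                seed=config.seed, spec=_OPLS_SPEC,
                                folds=config.cv_folds,
                                scaling=config.scaling_mode)
    uni = univariate_screen(table, pair,
                            log2fc_threshold=config.log2fc_threshold)
    decisions = select_pair_candidates(splot, vip, uni, config)
    return PairAnalysis(
        pair=pair, model=model, cv=cv,
        summary=model_summary(model, cv), splot=splot, vip=vip,
        jackknife=jk, permutation=perm, univariate=uni, decisions=decisions,
    )


def _oriented_splot(pa: PairAnalysis, reference: str) -> list[SPlotRow]:
    """S-plot rows re-oriented so positive p(corr) = elevated in the
    non-reference class of the contrast."""
    # fitted orientation: positive score side = lexicographically larger label
    flip = pa.pair[1] == reference
    if not flip:
        return pa.splot
    return [dataclasses.replace(r, p_corr=-r.p_corr, p_cov=-r.p_cov,
                                p_cov_raw=-r.p_cov_raw) for r in pa.splot]


def run_pipeline(
    table: FeatureTable,
    metas: list[CompoundMeta],
    config: PipelineConfig | None = None,
    run_permutation: bool = True,
) -> RunReport:
    """Execute the full marker-discovery workflow on a labeled table.

    Stages: OAV screen on region means → pairwise OPLS-DA + diagnostics and
    the four-filter cascade for every region pair → SUS plots per reference
    region → panel assembly (chemometric union ∩ OAV-primary) → multi-class
    PLS-DA classifier on the panel with a training confusion matrix.
    """
    config = config or PipelineConfig()
    regions = table.regions
    if len(regions) < 2:
        raise ValueError("pipeline needs at least two regions")

    logger.info("stage=oav rule=%s seed=%d", config.oav_rule, config.seed)
    summaries = summarize_by_region(table)
    by_name = {m.name: m for m in metas}
    missing = [n for n in table.compound_names if n not in by_name]
    if missing:
        raise ValueError(f"no metadata for compound(s): {missing}")
    metas_aligned = [by_name[n] for n in table.compound_names]
    oav_df = oav_table(summaries, metas_aligned, rule=config.oav_rule)
    primary = primary_aroma_screen(oav_records(summaries, metas_aligned),
                                   rule=config.oav_rule)

    pairs: dict[tuple[str, str], PairAnalysis] = {}
    for pair in itertools.combinations(regions, 2):
        logger.info("stage=opls pair=%s:%s folds=%d seed=%d", pair[0],
                    pair[1], config.cv_folds, config.seed)
        pairs[pair] = analyze_pair(table, pair, config, run_permutation)

    sus: dict[str, list[SUSRow]] = {}
    if len(regions) >= 3:
        for ref in regions:
            others = [r for r in regions if r != ref]
            pa1 = pairs[tuple(sorted((ref, others[0])))]
            pa2 = pairs[tuple(sorted((ref, others[1])))]
            sus[ref] = sus_plot(_oriented_splot(pa1, ref),
                                _oriented_splot(pa2, ref))

    logger.info("stage=panel pairs=%d", len(pairs))
    panel = assemble_panel({p: pa.decisions for p, pa in pairs.items()},
                           primary)

    classifier = None
    confusion = None
    if panel.final_panel:
        panel_names = [n for n in table.compound_names if n in panel.final_panel]
        logger.info("stage=classifier panel=%s lv=2 seed=%d", panel_names,
                    config.seed)
        panel_table = table.restrict_compounds(panel_names)
        classifier = fit_classifier(panel_table, n_lv=2,
                                    folds=config.cv_folds, seed=config.seed,
                                    scaling=config.scaling_mode)
        confusion = evaluate(classifier, panel_table)

    oav_dict = {
        name: {c: (None if v is None or (isinstance(v, float) and np.isnan(v))
                   else v)
               for c, v in row.items()}
        for name, row in oav_df.to_dict(orient="index").items()
    }
    return RunReport(
        config=config, oav=oav_dict, oav_primary=primary, pairs=pairs,
        sus=sus, panel=panel, classifier=classifier,
        confusion_training=confusion,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
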