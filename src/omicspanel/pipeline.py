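"""Config-driven orchestration of a two-group biomarker comparison.

The workflow mirrors the discovery design end to end: align samples ->
(optional sparse-taxon filter) -> autoscale -> PCA summary -> per-layer
stability selection and first-quartile cut -> per-layer panel evaluation ->
pooled second-stage selection over the union of selected features ->
combined-panel evaluation -> hemoglobin reference comparison -> cross-omics
correlation network.  Every random stage draws from a substream of the one
root seed, so reruns are byte-identical and stages are independently
re-runnable.

An outer stratified 75/25 split is drawn before any model sees the data:
all feature selection (per-layer and second-stage) runs on the outer
training samples, and every panel's reported test AUC scores the held-out
25%, which no selection step ever touched.  This keeps the test AUC an
honest estimate rather than a selection-biased one; the apparent
(full-data) AUC is reported alongside, labeled as such.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import network as net
from .panel import (
    DEFAULT_HEMOGLOBIN_IDS,
    PanelReport,
    evaluate_panel,
    reference_panel_auc,
)
from .selection import PenaltyConfig, StabilitySelection, run_stability, select_first_quartile
from .tables import (
    CohortMetadata,
    FeatureTable,
    TableError,
    align_samples,
    autoscale,
    filter_sparse_features,
    run_pca,
)

logger = logging.getLogger(__name__)

__all__ = ["ComparisonConfig", "ComparisonReport", "run_comparison", "second_stage_panel"]

# stage-indexed substreams of the root seed
_STREAM_STABILITY = 1
_STREAM_PANEL = 2
_STREAM_SECOND_STAGE = 3
_STREAM_REFERENCE = 4


@dataclass
class ComparisonConfig:
    """Settings of one two-group comparison."""

    groups: tuple[str, str]
    seed: int
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    sparse_filter: bool = False
    min_prevalence: float = 0.2
    relative_abundance_first: bool = False   # scale taxa proportions, not counts
    n_eval_iterations: int = 100
    r_min: float = 0.3
    p_max: float = 0.05
    correlation_method: str = "pearson"
    reference_ids: tuple[str, ...] = DEFAULT_HEMOGLOBIN_IDS
    reference_layer: str = "proteome"
    pca_components: int = 2
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ComparisonConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ComparisonConfig":
        raw = dict(raw)
        if "groups" not in raw or len(raw["groups"]) != 2:
            raise TableError("config must name exactly two groups")
        if "seed" not in raw:
            raise TableError("config must set a seed")
        raw["groups"] = tuple(raw["groups"])
        if "reference_ids" in raw:
            raw["reference_ids"] = tuple(raw["reference_ids"])
        pen = raw.pop("penalty", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TableError(f"unknown config key(s): {sorted(unknown)}")
        return cls(penalty=PenaltyConfig(**pen), **raw)


@dataclass
class ComparisonReport:
    """All artifacts of one comparison run."""

    config: ComparisonConfig
    selections: dict[str, StabilitySelection]
    layer_panels: dict[str, PanelReport]
    combined_selection: StabilitySelection | None
    combined_panel: PanelReport | None
    reference_panel: PanelReport | None
    omics_network: net.OmicsNetwork
    pca_summaries: dict[str, list[float]]
    run_log: list[dict] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for layer, sel in self.selections.items():
            sel.to_tsv(out / f"stability_{layer}.tsv", layer)
        for layer, rep in self.layer_panels.items():
            rep.to_json(out / f"panel_{layer}.json")
            rep.distributions_tsv(out / f"panel_{layer}_auc_distributions.tsv")
        if self.combined_selection is not None:
            self.combined_selection.to_tsv(out / "stability_combined.tsv", "combined")
        if self.combined_panel is not None:
            self.combined_panel.to_json(out / "panel_combined.json")
            self.combined_panel.distributions_tsv(
                out / "panel_combined_auc_distributions.tsv"
            )
        if self.reference_panel is not None:
            self.reference_panel.to_json(out / "panel_reference.json")
        self.omics_network.to_edge_tsv(out / "network_edges.tsv")
        self.omics_network.to_graphml(out / "network.graphml")
        (out / "pca_summary.json").write_text(
            json.dumps(self.pca_summaries, indent=2) + "\n"
        )
        # wall times live only here; everything else is byte-reproducible
        (out / "run_log.json").write_text(json.dumps(self.run_log, indent=2) + "\n")


def _layer_seed(root_seed: int, stream: int, layer_idx: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(stream, layer_idx))


def second_stage_panel(
    selected_per_layer: dict[str, list[str]],
    normalized: dict[str, FeatureTable],
    y: np.ndarray,
    config: ComparisonConfig,
    eval_split: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[StabilitySelection, PanelReport, pd.DataFrame]:
    """Re-run stability selection on the pooled selected features.

    The union of the per-layer first-quartile features is concatenated into
    one autoscaled matrix and the same selection-then-model procedure is
    applied again; this second pass is what produces the small cross-omics
    panels.  With ``eval_split`` given, selection runs on the training rows
    only and the panel's test AUC scores the held-out rows.  Returns the
    second-stage selection, the combined-panel report, and the pooled
    feature matrix used.
    """
    blocks, ids, layers = [], [], []
    for layer, feats in selected_per_layer.items():
        if not feats:
            continue
        t = normalized[layer]
        present = [f for f in feats if f in t.values.columns]
        blocks.append(t.values.loc[:, present])
        ids.extend(present)
        layers.extend([layer] * len(present))
    if not ids:
        raise ValueError("second_stage_panel: union of selected features is empty")
    pooled = pd.concat(blocks, axis=1)
    ss_cfg = dataclasses.replace(
        config.penalty,
        seed=int(_layer_seed(config.seed, _STREAM_SECOND_STAGE).generate_state(1)[0] % (2**31)),
    )
    sel_rows = np.arange(len(y)) if eval_split is None else eval_split[0]
    if len(ids) == 1:
        # nothing to select among; the single feature is the panel
        sel = None
        panel_feats = ids
    else:
        sel = run_stability(
            pooled.to_numpy(dtype=float)[sel_rows], y[sel_rows], ss_cfg, ids
        )
        panel_feats = sel.selected_features
        if not panel_feats:
            panel_feats = ids
    rng = np.random.default_rng(_layer_seed(config.seed, _STREAM_SECOND_STAGE, 1))
    report = evaluate_panel(
        pooled.loc[:, panel_feats].to_numpy(dtype=float),
        y,
        panel_feats,
        n_iterations=config.n_eval_iterations,
        rng=rng,
        eval_split=eval_split,
    )
    return sel, report, pooled


def run_comparison(
    config: ComparisonConfig,
    tables: Sequence[FeatureTable],
    metadata: CohortMetadata,
) -> ComparisonReport:
    """Execute the full comparison workflow; see the module docstring."""
    log: list[dict] = []

    def _stage(name: str, t0: float, **extra) -> None:
        entry = {"stage": name, "wall_s": round(time.perf_counter() - t0, 3)}
        entry.update(extra)
        log.append(entry)
        logger.info("stage %s done (%.2fs)", name, entry["wall_s"])

    try:
        t0 = time.perf_counter()
        aligned, meta = align_samples(list(tables), metadata, config.groups)
        y = (meta.groups == config.groups[0]).to_numpy().astype(int)
        # outer evaluation split: the held-out 25% is never seen by any
        # selection stage, so reported test AUCs are selection-unbiased
        from sklearn.model_selection import train_test_split

        split_seed = int(
            _layer_seed(config.seed, 0).generate_state(1)[0] % (2**31)
        )
        outer_tr, outer_te = train_test_split(
            np.arange(len(y)), test_size=0.25, stratify=y, random_state=split_seed
        )
        outer_tr, outer_te = np.sort(outer_tr), np.sort(outer_te)
        _stage("align", t0, n_samples=len(y), n_train=len(outer_tr),
               n_test=len(outer_te))

        t0 = time.perf_counter()
        prepped = {}
        for t in aligned:
            if config.sparse_filter:
                t = filter_sparse_features(t, config.min_prevalence)
            if config.relative_abundance_first and t.layer_name == "microbiota":
                from .tables import relative_abundance

                t = relative_abundance(t)
            prepped[t.layer_name] = t
        normalized = {name: autoscale(t) for name, t in prepped.items()}
        _stage("preprocess", t0,
               n_features={k: v.n_features for k, v in normalized.items()})

        t0 = time.perf_counter()
        pca_summaries = {}
        for name, t in normalized.items():
            k = min(config.pca_components, t.n_samples - 1, t.n_features)
            pca_summaries[name] = [
                float(v) for v in run_pca(t, k).explained_variance_fractions
            ]
        _stage("pca", t0)

        selections: dict[str, StabilitySelection] = {}
        layer_panels: dict[str, PanelReport] = {}
        for li, (name, t) in enumerate(normalized.items()):
            t0 = time.perf_counter()
            cfg = dataclasses.replace(
                config.penalty,
                seed=int(
                    _layer_seed(config.seed, _STREAM_STABILITY, li).generate_state(1)[0]
                    % (2**31)
                ),
            )
            sel = run_stability(t.matrix[outer_tr], y[outer_tr], cfg, t.feature_ids)
            selections[name] = sel
            chosen = sel.selected_features
            _stage(f"stability_{name}", t0, n_selected=len(chosen))
            if chosen:
                t0 = time.perf_counter()
                rng = np.random.default_rng(_layer_seed(config.seed, _STREAM_PANEL, li))
                layer_panels[name] = evaluate_panel(
                    t.values.loc[:, chosen].to_numpy(dtype=float),
                    y,
                    chosen,
                    n_iterations=config.n_eval_iterations,
                    rng=rng,
                    eval_split=(outer_tr, outer_te),
                )
                _stage(f"panel_{name}", t0)

        t0 = time.perf_counter()
        selected_per_layer = {k: v.selected_features for k, v in selections.items()}
        combined_sel, combined_panel, pooled = second_stage_panel(
            selected_per_layer, normalized, y, config, eval_split=(outer_tr, outer_te)
        )
        _stage("second_stage", t0,
               n_panel=len(combined_panel.model.feature_ids))

        reference_report = None
        if config.reference_layer in normalized:
            ref_table = normalized[config.reference_layer]
            present = [f for f in config.reference_ids if f in ref_table.values.columns]
            if present:
                t0 = time.perf_counter()
                rng = np.random.default_rng(_layer_seed(config.seed, _STREAM_REFERENCE))
                reference_report = reference_panel_auc(
                    ref_table, y, config.reference_ids,
                    n_iterations=config.n_eval_iterations, rng=rng,
                    eval_split=(outer_tr, outer_te),
                )
                _stage("reference_panel", t0)
            else:
                log.append({"stage": "reference_panel", "skipped":
                            "no reference IDs present"})

        t0 = time.perf_counter()
        layer_of = {}
        for layer, feats in selected_per_layer.items():
            for f in feats:
                layer_of[f] = layer
        if layer_of:
            pooled_all = pooled
            r, p = net.correlate_selected(pooled_all, config.correlation_method)
            edges = net.filter_edges(
                r, p, layer_of, config.r_min, config.p_max, config.correlation_method
            )
            omics_network = net.build_network(
                edges, layer_of, config.r_min, config.p_max, config.correlation_method
            )
        else:
            omics_network = net.build_network([], {}, config.r_min, config.p_max,
                                              config.correlation_method)
        _stage("network", t0, n_edges=omics_network.n_edges)
    except Exception as exc:
        stage = log[-1]["stage"] if log else "start"
        raise RuntimeError(
            f"comparison {config.groups} failed after stage {stage!r}: {exc}"
        ) from exc

    report = ComparisonReport(
        config=config,
        selections=selections,
        layer_panels=layer_panels,
        combined_selection=combined_sel,
        combined_panel=combined_panel,
        reference_panel=reference_report,
        omics_network=omics_network,
        pca_summaries=pca_summaries,
        run_log=log,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
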