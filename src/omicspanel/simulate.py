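"""Synthetic matched case-control multi-omics cohort generator.

Emulates a fecal biomarker study design with three layers measured on the
same samples:

* ``microbiota`` — 16S taxon counts.  Per-sample sequencing depth is drawn
  from a log-normal depth model; compositions are Dirichlet-multinomial
  around a heavy-tailed baseline profile, with planted group effects applied
  as log-fold changes to the Dirichlet mean *before* renormalization (the
  induced effects are therefore compositional, not absolute).
* ``proteome`` — spectral counts.  Each protein's count given the sample
  total is beta-binomial around a baseline proportion; planted effects
  multiply the proportion.
* ``amino_acid`` — concentrations.  Log-normal per feature with planted
  shifts on the log scale and a missing-at-random quantification mask
  (missing values are recorded as 0).

Latent factors shared across layers induce known pairwise correlations for
network ground truth.  Everything is driven by a single root seed with
per-layer substreams, so the output is bit-reproducible and layers can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import GROUPS, CohortMetadata, FeatureTable

__all__ = [
    "LayerSpec",
    "PlantedSignal",
    "LatentFactorSpec",
    "CohortDesign",
    "SyntheticTruth",
    "default_design",
    "generate_cohort",
    "sample_microbiome_layer",
    "sample_proteome_layer",
    "sample_amino_acid_layer",
    "inject_latent_factors",
    "loading_for_target_r",
]

LAYER_NAMES = ("microbiota", "proteome", "amino_acid")


class DesignError(ValueError):
    """Raised when a cohort design violates its invariants."""


@dataclass
class LayerSpec:
    """Shape and distributional parameters of one omics layer.

    ``depth_location`` / ``depth_sigma`` parameterize a log-normal
    per-sample total for count layers (location = log median depth).
    ``overdispersion`` is the extra-multinomial/extra-binomial dispersion:
    0 recovers the pure multinomial (taxa) or binomial (proteome) limit.
    For the concentration layer, ``log_sigma`` is the per-feature log-scale
    SD and ``detect_prob`` the per-feature quantification probability.
    """

    layer_name: str
    n_features: int
    baseline_profile: np.ndarray
    depth_location: float = 0.0
    depth_sigma: float = 0.0
    overdispersion: float = 0.0
    log_sigma: np.ndarray | None = None
    detect_prob: np.ndarray | None = None
    feature_prefix: str = "F"

    def __post_init__(self) -> None:
        if self.layer_name not in LAYER_NAMES:
            raise DesignError(f"unknown layer_name {self.layer_name!r}")
        if self.n_features < 1:
            raise DesignError("n_features must be >= 1")
        self.baseline_profile = np.asarray(self.baseline_profile, float)
        if len(self.baseline_profile) != self.n_features:
            raise DesignError(
                f"baseline_profile length {len(self.baseline_profile)} != "
                f"n_features {self.n_features} in layer {self.layer_name!r}"
            )
        if self.overdispersion < 0:
            raise DesignError("overdispersion must be nonnegative")
        if self.layer_name in ("microbiota", "proteome") and (
            not np.isfinite(self.depth_location) or np.exp(self.depth_location) <= 0
        ):
            raise DesignError("count layers need a strictly positive expected depth")
        if self.log_sigma is not None:
            self.log_sigma = np.asarray(self.log_sigma, float)
            if np.any(self.log_sigma < 0):
                raise DesignError("log_sigma entries must be nonnegative")

    def feature_ids(self) -> list[str]:
        return [f"{self.feature_prefix}{j + 1:04d}" for j in range(self.n_features)]


@dataclass
class PlantedSignal:
    """A known group effect on one feature.

    ``effect_size`` is a log-fold change for count layers and a
    standardized mean shift (in units of the feature's log-scale SD) for
    the concentration layer.  The effect is applied to samples of
    ``contrast[0]`` relative to everyone else; ``effect_size = 0`` leaves
    the feature exchangeable.
    """

    layer_name: str
    feature_index: int
    contrast: tuple[str, str]
    effect_size: float


@dataclass
class LatentFactorSpec:
    """Shared latent variable inducing cross-feature correlations.

    ``loadings`` is a list of ``(layer_name, feature_index, loading)``; the
    factor is standard normal scaled by ``sqrt(factor_variance)`` per
    sample, and each loaded feature receives ``loading * factor`` additively
    on its value scale.
    """

    loadings: list[tuple[str, int, float]]
    factor_variance: float = 1.0

    def __post_init__(self) -> None:
        if self.factor_variance < 0:
            raise DesignError("factor_variance must be nonnegative")


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort."""

    group_sizes: dict[str, int]
    layers: list[LayerSpec]
    planted: list[PlantedSignal] = field(default_factory=list)
    latent_factors: list[LatentFactorSpec] = field(default_factory=list)
    seed: int = 0
    # covariate model: (mean, sd) for age and BMI; probabilities otherwise
    age_mean: float = 68.0
    age_sd: float = 6.0
    bmi_mean: float = 26.0
    bmi_sd: float = 2.5
    male_prob: float = 0.6
    smoking_probs: tuple[float, float, float] = (0.2, 0.65, 0.15)  # never/stopped/active

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise DesignError(f"unknown group {g!r} in group_sizes")
            if n < 2:
                raise DesignError(f"group {g!r} must have >= 2 samples")
        names = [l.layer_name for l in self.layers]
        if len(set(names)) != len(names):
            raise DesignError("duplicate layer names")
        by_name = {l.layer_name: l for l in self.layers}
        for sig in self.planted:
            if sig.layer_name not in by_name:
                raise DesignError(
                    f"planted signal references unknown layer {sig.layer_name!r}"
                )
            if not 0 <= sig.feature_index < by_name[sig.layer_name].n_features:
                raise DesignError(
                    f"planted feature_index {sig.feature_index} out of range "
                    f"for layer {sig.layer_name!r}"
                )
            for g in sig.contrast:
                if g not in self.group_sizes:
                    raise DesignError(
                        f"planted contrast group {g!r} absent from group_sizes"
                    )
        for fac in self.latent_factors:
            for layer, j, _ in fac.loadings:
                if layer not in by_name:
                    raise DesignError(
                        f"latent factor loads unknown layer {layer!r}"
                    )
                if not 0 <= j < by_name[layer].n_features:
                    raise DesignError(
                        f"latent factor loads feature {j} out of range in {layer!r}"
                    )

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``planted`` maps a contrast to the planted feature IDs (with layer);
    ``expected_edges`` lists ``(id_a, layer_a, id_b, layer_b, expected_r)``
    for every latent-factor feature pair.
    """

    planted: pd.DataFrame      # columns: layer, feature_id, contrast_a, contrast_b, effect_size
    expected_edges: pd.DataFrame  # columns: feature_a, layer_a, feature_b, layer_b, expected_r

    def planted_ids(self, layer: str | None = None) -> list[str]:
        df = self.planted
        if layer is not None:
            df = df[df["layer"] == layer]
        return list(df["feature_id"])

    def write(self, planted_path, edges_path) -> None:
        self.planted.to_csv(planted_path, sep="\t", index=False)
        self.expected_edges.to_csv(edges_path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Default design


def default_design(seed: int = 0) -> CohortDesign:
    """The default synthetic cohort: 12 CRC / 21 adenoma / 20 control samples,
    225 taxa (log-normal depth, median 23,041 reads), 521 proteins tuned to a
    median of roughly 169 detected per sample, and 44 amino acids tuned to a
    median of roughly 26 quantified per sample.

    Baseline profiles are drawn once from heavy-tailed distributions using a
    substream of ``seed`` so the design itself is reproducible.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(104729,))
    r_taxa, r_prot, r_aa = [np.random.default_rng(s) for s in ss.spawn(3)]

    taxa_baseline = r_taxa.lognormal(mean=0.0, sigma=2.0, size=225)
    taxa = LayerSpec(
        "microbiota", 225, taxa_baseline,
        depth_location=float(np.log(23041)), depth_sigma=0.35,
        overdispersion=0.02, feature_prefix="OTU",
    )

    # skewed proportions with a detection floor tuned so roughly 169 of the
    # 521 proteins carry a nonzero spectral count in a typical sample
    prot_baseline = r_prot.lognormal(mean=0.0, sigma=1.3, size=521)
    prot_baseline /= prot_baseline.sum()
    proteome = LayerSpec(
        "proteome", 521, prot_baseline,
        depth_location=float(np.log(3000)), depth_sigma=0.35,
        overdispersion=0.01, feature_prefix="PROT",
    )

    aa_baseline = np.exp(r_aa.normal(3.0, 1.0, size=44))  # median conc. scale
    aa = LayerSpec(
        "amino_acid", 44, aa_baseline,
        log_sigma=np.full(44, 0.5),
        detect_prob=np.clip(r_aa.beta(3.0, 2.0, size=44), 0.05, 0.98),
        feature_prefix="AA",
    )
    return CohortDesign(
        group_sizes={"CRC": 12, "adenoma": 21, "control": 20},
        layers=[taxa, proteome, aa],
        seed=seed,
    )


def design_from_dict(raw: dict) -> CohortDesign:
    """Build a CohortDesign from a parsed YAML/JSON mapping.

    Recognized keys: ``seed``, ``group_sizes``, ``planted`` (list of
    ``{layer, feature_index, contrast: [case, reference], effect_size}``),
    and ``latent_factors`` (list of ``{loadings: [[layer, index, loading],
    ...], factor_variance}``).  Layer shapes and distributional defaults are
    those of :func:`default_design`.
    """
    raw = dict(raw or {})
    known = {"seed", "group_sizes", "planted", "latent_factors"}
    unknown = set(raw) - known
    if unknown:
        raise DesignError(f"unknown design key(s): {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    design = default_design(seed)
    planted = [
        PlantedSignal(
            layer_name=s["layer"],
            feature_index=int(s["feature_index"]),
            contrast=(s["contrast"][0], s["contrast"][1]),
            effect_size=float(s["effect_size"]),
        )
        for s in raw.get("planted", [])
    ]
    factors = [
        LatentFactorSpec(
            loadings=[(l[0], int(l[1]), float(l[2])) for l in f["loadings"]],
            factor_variance=float(f.get("factor_variance", 1.0)),
        )
        for f in raw.get("latent_factors", [])
    ]
    return replace(
        design,
        group_sizes=dict(raw.get("group_sizes", design.group_sizes)),
        planted=planted,
        latent_factors=factors,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Metadata / covariates


def _make_metadata(design: CohortDesign, rng: np.random.Generator) -> CohortMetadata:
    rows = []
    i = 0
    for group in design.group_sizes:  # insertion order: deterministic
        for _ in range(design.group_sizes[group]):
            i += 1
            rows.append(
                {
                    "sample_id": f"S{i:03d}",
                    "group": group,
                    "age": float(np.round(rng.normal(design.age_mean, design.age_sd), 1)),
                    "sex": "male" if rng.random() < design.male_prob else "female",
                    "bmi": float(np.round(rng.normal(design.bmi_mean, design.bmi_sd), 1)),
                    "smoking": ["never", "stopped", "active"][
                        rng.choice(3, p=design.smoking_probs)
                    ],
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    return CohortMetadata(df)


def _planted_multiplier(
    spec: LayerSpec,
    planted: Sequence[PlantedSignal],
    groups: pd.Series,
) -> np.ndarray:
    """(n_samples, n_features) multiplicative effect matrix, exp(effect) for
    samples of each signal's contrast[0] group."""
    mult = np.ones((len(groups), spec.n_features))
    for sig in planted:
        if sig.layer_name != spec.layer_name:
            continue
        in_case = (groups == sig.contrast[0]).to_numpy()
        mult[in_case, sig.feature_index] *= np.exp(sig.effect_size)
    return mult


def _draw_depths(spec: LayerSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-sample totals: rounded log-normal; zero draws are redrawn."""
    depths = np.zeros(n, dtype=np.int64)
    todo = np.arange(n)
    while todo.size:
        draw = np.round(
            rng.lognormal(spec.depth_location, spec.depth_sigma, size=todo.size)
        ).astype(np.int64)
        depths[todo] = draw
        todo = todo[draw <= 0]
    return depths


# ---------------------------------------------------------------------------
# Layer samplers


def sample_microbiome_layer(
    spec: LayerSpec,
    meta: CohortMetadata,
    planted: Sequence[PlantedSignal],
    rng: np.random.Generator,
) -> FeatureTable:
    """Dirichlet-multinomial taxon counts with compositional planted effects.

    The Dirichlet concentration is ``p / overdispersion`` (p the renormalized
    baseline including planted log-fold effects); ``overdispersion = 0``
    collapses to a pure multinomial draw.
    """
    if spec.layer_name != "microbiota":
        raise DesignError("sample_microbiome_layer expects layer_name='microbiota'")
    n = len(meta.sample_ids)
    depths = _draw_depths(spec, n, rng)
    mult = _planted_multiplier(spec, planted, meta.groups)
    base = np.clip(spec.baseline_profile, 1e-300, None)
    counts = np.empty((n, spec.n_features), dtype=np.int64)
    for i in range(n):
        p = base * mult[i]
        p = p / p.sum()
        if spec.overdispersion > 0:
            p = rng.dirichlet(p / spec.overdispersion)
        counts[i] = rng.multinomial(depths[i], p)
    df = pd.DataFrame(counts, index=meta.sample_ids, columns=spec.feature_ids())
    return FeatureTable("microbiota", df, "count")


def sample_proteome_layer(
    spec: LayerSpec,
    meta: CohortMetadata,
    planted: Sequence[PlantedSignal],
    rng: np.random.Generator,
) -> FeatureTable:
    """Beta-binomial spectral counts given per-sample totals.

    Each feature j with baseline proportion p_j draws, per sample, a
    proportion from Beta with mean p_j and overdispersion rho
    (rho = 1/(a+b+1); rho = 0 is binomial), then a binomial count given the
    sample total.  Planted effects multiply p_j for the contrast group.
    """
    if spec.layer_name != "proteome":
        raise DesignError("sample_proteome_layer expects layer_name='proteome'")
    n = len(meta.sample_ids)
    depths = _draw_depths(spec, n, rng)
    mult = _planted_multiplier(spec, planted, meta.groups)
    p = np.clip(spec.baseline_profile[None, :] * mult, 1e-12, 1 - 1e-12)
    rho = spec.overdispersion
    if rho > 0:
        s = (1.0 - rho) / rho
        p_draw = rng.beta(p * s, (1.0 - p) * s)
    else:
        p_draw = np.broadcast_to(p, (n, spec.n_features)).copy()
    counts = rng.binomial(depths[:, None], p_draw)
    df = pd.DataFrame(counts, index=meta.sample_ids, columns=spec.feature_ids())
    return FeatureTable("proteome", df, "count")


def sample_amino_acid_layer(
    spec: LayerSpec,
    meta: CohortMetadata,
    planted: Sequence[PlantedSignal],
    rng: np.random.Generator,
) -> FeatureTable:
    """Log-normal concentrations with an MAR quantification mask.

    Planted ``effect_size`` shifts the feature's log-mean by
    ``effect_size * log_sigma`` (a standardized shift).  Non-quantified
    entries are recorded as 0, matching how missing amino-acid measurements
    are encoded on input.
    """
    if spec.layer_name != "amino_acid":
        raise DesignError("sample_amino_acid_layer expects layer_name='amino_acid'")
    n = len(meta.sample_ids)
    sigma = spec.log_sigma if spec.log_sigma is not None else np.full(spec.n_features, 0.5)
    mu = np.log(np.clip(spec.baseline_profile, 1e-300, None))
    shift = np.zeros((n, spec.n_features))
    for sig in planted:
        if sig.layer_name != "amino_acid":
            continue
        in_case = (meta.groups == sig.contrast[0]).to_numpy()
        shift[in_case, sig.feature_index] += sig.effect_size * sigma[sig.feature_index]
    conc = np.exp(rng.normal(mu[None, :] + shift, sigma[None, :]))
    if spec.detect_prob is not None:
        mask = rng.random((n, spec.n_features)) < spec.detect_prob[None, :]
        conc = conc * mask
    df = pd.DataFrame(conc, index=meta.sample_ids, columns=spec.feature_ids())
    return FeatureTable("amino_acid", df, "concentration")


# ---------------------------------------------------------------------------
# Latent factors


def loading_for_target_r(sd: float, target_r: float, factor_variance: float = 1.0) -> float:
    """Loading making a feature of residual SD ``sd`` correlate at
    ``sqrt(target_r)``-share with the factor, so two features built this way
    have expected pairwise correlation ``target_r``."""
    if not 0 <= target_r < 1:
        raise ValueError("target_r must lie in [0, 1)")
    return sd * np.sqrt(target_r / (1.0 - target_r)) / np.sqrt(factor_variance)


def inject_latent_factors(
    tables: Sequence[FeatureTable],
    factors: Sequence[LatentFactorSpec],
    rng: np.random.Generator,
) -> tuple[list[FeatureTable], pd.DataFrame]:
    """Perturb loaded features with shared per-sample factors.

    The factor value is added to the feature's stored values scaled by its
    loading (counts are rounded and clipped at 0).  For every pair of
    features loaded on the same factor the expected Pearson correlation is
    recorded, computed in closed form from the loadings, the factor
    variance, and the features' pre-injection empirical variances:

        r_ab = (l_a l_b V) / sqrt((l_a^2 V + s_a^2)(l_b^2 V + s_b^2))

    Returns the perturbed tables and the expected-edge table.
    """
    by_layer = {t.layer_name: t.copy() for t in tables}
    if len(by_layer) != len(tables):
        raise DesignError("duplicate layer names in tables")
    n = len(tables[0].sample_ids)
    edges = []
    for fac in factors:
        for layer, j, _ in fac.loadings:
            if layer not in by_layer:
                raise DesignError(f"latent factor loads unknown layer {layer!r}")
            if not 0 <= j < by_layer[layer].n_features:
                raise DesignError(f"feature index {j} out of range in {layer!r}")
        f = rng.normal(0.0, 1.0, size=n) * np.sqrt(fac.factor_variance)
        pre_sd = {}
        for layer, j, loading in fac.loadings:
            t = by_layer[layer]
            col = t.values.iloc[:, j].to_numpy(dtype=float)
            pre_sd[(layer, j)] = col.std(ddof=1)
            col = col + loading * f
            if t.value_kind == "count":
                col = np.clip(np.round(col), 0, None).astype(np.int64)
            t.values.isetitem(j, col)
        V = fac.factor_variance
        loads = fac.loadings
        for a in range(len(loads)):
            for b in range(a + 1, len(loads)):
                (la_l, la_j, la), (lb_l, lb_j, lb) = loads[a], loads[b]
                if (la_l, la_j) == (lb_l, lb_j):
                    continue
                sa, sb = pre_sd[(la_l, la_j)], pre_sd[(lb_l, lb_j)]
                denom = np.sqrt((la**2 * V + sa**2) * (lb**2 * V + sb**2))
                r = (la * lb * V) / denom if denom > 0 else 0.0
                edges.append(
                    {
                        "feature_a": by_layer[la_l].feature_ids[la_j],
                        "layer_a": la_l,
                        "feature_b": by_layer[lb_l].feature_ids[lb_j],
                        "layer_b": lb_l,
                        "expected_r": float(r),
                    }
                )
    edge_df = pd.DataFrame(
        edges, columns=["feature_a", "layer_a", "feature_b", "layer_b", "expected_r"]
    )
    return [by_layer[t.layer_name] for t in tables], edge_df


# ---------------------------------------------------------------------------
# Top-level generation


_SAMPLERS = {
    "microbiota": sample_microbiome_layer,
    "proteome": sample_proteome_layer,
    "amino_acid": sample_amino_acid_layer,
}


def generate_cohort(
    design: CohortDesign,
) -> tuple[list[FeatureTable], CohortMetadata, SyntheticTruth]:
    """Generate the full cohort: one table per layer, shared sample IDs,
    metadata, and the ground truth (planted IDs and expected correlations).

    Identical designs (including seed) produce bit-identical output.
    """
    root = np.random.SeedSequence(design.seed)
    streams = root.spawn(len(design.layers) + 2)
    meta = _make_metadata(design, np.random.default_rng(streams[0]))
    tables = []
    for k, spec in enumerate(design.layers):
        rng = np.random.default_rng(streams[1 + k])
        tables.append(_SAMPLERS[spec.layer_name](spec, meta, design.planted, rng))
    factor_rng = np.random.default_rng(streams[-1])
    tables, edge_df = inject_latent_factors(tables, design.latent_factors, factor_rng)

    by_layer = {t.layer_name: t for t in tables}
    planted_rows = [
        {
            "layer": sig.layer_name,
            "feature_id": by_layer[sig.layer_name].feature_ids[sig.feature_index],
            "contrast_a": sig.contrast[0],
            "contrast_b": sig.contrast[1],
            "effect_size": sig.effect_size,
        }
        for sig in design.planted
    ]
    truth = SyntheticTruth(
        planted=pd.DataFrame(
            planted_rows,
            columns=["layer", "feature_id", "contrast_a", "contrast_b", "effect_size"],
        ),
        expected_edges=edge_df,
    )
    return tables, meta, truth
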