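"""End-to-end analysis driver on synthetic data.

``run_full_pipeline`` composes the whole analysis graph: shape-set synthesis
-> pixel features -> synthetic neural population (selectivity-screened) and
surrogate layer stacks (geometry-ramped "trained" vs pixel-locked
"untrained") -> RDMs -> layer-wise bootstrap RSA with shared replicates,
paired trained-vs-untrained tests and FDR -> split-half noise ceiling ->
size-reduction comparison -> subsampling and PCA curves for the peak layer ->
group profiles, cross-system profile correlations, and the exact
curved-vs-straight test. Outputs are tidy CSV tables plus one JSON report,
every artifact stamped with the config hash and master seed; a fixed seed
reproduces all tabular outputs byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _pkg_version
from ._utils import child_seed, stable_hash
from .contrasts import (curved_straight_test, group_pair_distances,
                        human_profile_from_rdm, profile_correlation)
from .dimensionality import pca_similarity_curve, subsample_similarity
from .features import filter_differential_units, pixel_features
from .rdm import compute_rdm, save_rdm
from .rsa import bootstrap_rsa, fdr_correct, paired_bootstrap_test, split_half_ceiling
from .stimuli import StimulusConfig, balance_pixel_differences, build_shape_set, save_shape_set
from .synth import (make_geometry_profile, make_sorting_probabilities,
                    simulate_layer_stack, simulate_neurons, simulate_sorting,
                    screen_selective_units, GeometryProfile)


class GeneratorSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_units: int = 119
    noise_scale: float = 1.0
    trials_min: int = 5
    trials_median: int = 10
    n_layers: int = 8
    units_per_layer: list[int] | None = None
    redundancy: int = 4
    n_subjects: int = 23

    def units(self) -> list[int]:
        return self.units_per_layer or [400] * self.n_layers


class StimulusConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    canvas_size: int = 96
    background_level: int = 128
    fill_level: int = 255
    scale_factor: float = 1.0

    def to_stimulus_config(self, scale: float | None = None) -> StimulusConfig:
        return StimulusConfig(
            canvas_size=self.canvas_size, background_level=self.background_level,
            fill_level=self.fill_level,
            scale_factor=self.scale_factor if scale is None else scale,
        )


class AnalysisConfig(BaseModel):
    """Strictly validated configuration of the full pipeline; unknown keys
    are rejected and the config hash is recorded in every output."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    stimulus: StimulusConfigModel = Field(default_factory=StimulusConfigModel)
    generator: GeneratorSettings = Field(default_factory=GeneratorSettings)
    metric: str = "normalized_euclidean"
    n_boot: int = 10_000
    n_splits: int = 10_000
    fractions: list[float] = Field(default_factory=lambda: [0.1, 1.0, 10.0, 100.0])
    n_subsample: int = 10_000
    max_k: int = 20
    q_level: float = 0.05
    target_geometry: str = "neural_profile"  # or "pixel" (negative control)
    balance_stimuli: bool = True
    compare_scales: list[float] = Field(default_factory=lambda: [1.0, 0.5])
    write_pngs: bool = True

    def hash(self) -> str:
        return stable_hash(self.model_dump())


def _trained_mixing(n_layers: int) -> list[float]:
    return list(np.linspace(0.0, 1.0, n_layers))


def _layer_rdms(layers, metric):
    rdms = []
    for lm in layers:
        r = compute_rdm(filter_differential_units(lm), metric)
        r.layer_id = lm.source_tag  # annotate for result labelling
        rdms.append(r)
    return rdms


def _build_target(config: AnalysisConfig, shape_set, pixel_rdm) -> GeometryProfile:
    if config.target_geometry == "pixel":
        return GeometryProfile(pixel_rdm, {"note": "pixel negative control"})
    if config.target_geometry != "neural_profile":
        raise ValueError(f"unknown target_geometry {config.target_geometry!r}")
    return make_geometry_profile(shape_set.ids(), seed=child_seed(config.seed, "neurons"))


def run_full_pipeline(config: AnalysisConfig, out_dir) -> dict:
    """Run every analysis stage on synthetic data and write the report bundle.

    Returns the report dict (also written to ``report.json``); CSV tables and
    stimulus PNGs land in ``out_dir``. Any stage failure raises with the
    stage name and config hash attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    stamp = {"config_hash": chash, "seed": config.seed, "version": _pkg_version}
    report: dict = {**stamp, "stages": {}}
    stage = "init"
    try:
        # --- stimuli -------------------------------------------------------
        stage = "stimuli"
        scfg = config.stimulus.to_stimulus_config()
        shape_set = build_shape_set(scfg, seed=child_seed(config.seed, "stimuli"))
        if config.balance_stimuli:
            shape_set = balance_pixel_differences(shape_set, tolerance=0.1, max_iter=15)
        save_shape_set(shape_set, out / "stimuli", write_png=config.write_pngs)
        report["stages"]["stimuli"] = {
            "n_stimuli": len(shape_set.stimuli),
            "balance": shape_set.balance_report,
        }

        # --- features and targets -----------------------------------------
        stage = "features"
        pix = pixel_features(shape_set.images(), shape_set.ids())
        pixel_rdm = compute_rdm(pix, "normalized_euclidean")
        save_rdm(pixel_rdm, out / "pixel_rdm.csv")
        profile = _build_target(config, shape_set, pixel_rdm)

        # --- synthetic neurons --------------------------------------------
        stage = "neurons"
        gen = config.generator
        dataset = simulate_neurons(
            shape_set.ids(), profile, n_units=gen.n_units,
            trials={"min": gen.trials_min, "median": gen.trials_median},
            noise_scale=gen.noise_scale, seed=child_seed(config.seed, "neurons"),
        )
        dataset = screen_selective_units(dataset, alpha=0.05)
        neural_rdm = compute_rdm(dataset.to_activation_matrix(), config.metric)
        save_rdm(neural_rdm, out / "neural_rdm.csv")
        report["stages"]["neurons"] = {
            "n_selective_units": dataset.n_units,
            "n_units_simulated": gen.n_units,
        }

        # --- layer stacks --------------------------------------------------
        stage = "layers"
        units = gen.units()
        mixing = _trained_mixing(gen.n_layers)
        lseed = child_seed(config.seed, "layers")
        trained = simulate_layer_stack(pix, profile.target_rdm, gen.n_layers, units,
                                       mixing, redundancy=gen.redundancy, seed=lseed)
        untrained = simulate_layer_stack(pix, profile.target_rdm, gen.n_layers, units,
                                         [0.0] * gen.n_layers,
                                         redundancy=gen.redundancy, seed=lseed)
        for k, lm in enumerate(trained):
            lm.source_tag = f"trained-{k + 1}"
        for k, lm in enumerate(untrained):
            lm.source_tag = f"untrained-{k + 1}"
        trained_rdms = _layer_rdms(trained, config.metric)
        untrained_rdms = _layer_rdms(untrained, config.metric)

        # --- layer-wise RSA with shared replicates ------------------------
        stage = "rsa"
        bseed = child_seed(config.seed, "bootstrap")
        results = bootstrap_rsa(dataset, trained_rdms + untrained_rdms,
                                metric=config.metric, n_boot=config.n_boot, seed=bseed)
        res_tr = results[: gen.n_layers]
        res_un = results[gen.n_layers:]
        pvals = [paired_bootstrap_test(a, b).p for a, b in zip(res_tr, res_un)]
        sig, qvals = fdr_correct(pvals, q_level=config.q_level)
        rows = []
        for k in range(gen.n_layers):
            rows.append(dict(layer=k + 1, variant="trained", rho=res_tr[k].rho,
                             ci_low=res_tr[k].ci_low, ci_high=res_tr[k].ci_high,
                             p_vs_untrained=pvals[k], q=qvals[k], significant=bool(sig[k])))
            rows.append(dict(layer=k + 1, variant="untrained", rho=res_un[k].rho,
                             ci_low=res_un[k].ci_low, ci_high=res_un[k].ci_high,
                             p_vs_untrained=np.nan, q=np.nan, significant=False))
        rsa_df = pd.DataFrame(rows)
        rsa_df.to_csv(out / "rsa.csv", index=False, float_format="%.10g")
        trained_rhos = [r.rho for r in res_tr]
        peak = int(np.argmax(trained_rhos))
        report["stages"]["rsa"] = {
            "trained_rho": trained_rhos,
            "untrained_rho": [r.rho for r in res_un],
            "peak_layer": peak + 1,
            "n_significant_trained_vs_untrained": int(sig.sum()),
            "curve_range_trained": float(np.max(trained_rhos) - np.min(trained_rhos)),
        }

        # --- noise ceiling -------------------------------------------------
        stage = "noise_ceiling"
        ceiling = split_half_ceiling(dataset, metric=config.metric,
                                     n_splits=config.n_splits,
                                     seed=child_seed(config.seed, "splits"))
        report["stages"]["noise_ceiling"] = {
            "median": ceiling.median, "lo": ceiling.lo, "hi": ceiling.hi,
            "n_splits": ceiling.n_splits,
        }

        # --- size comparison ----------------------------------------------
        if len(config.compare_scales) >= 2:
            stage = "sizes"
            sizes_df = compare_sizes(config, config.compare_scales,
                                     _dataset=dataset, _profile=profile)
            sizes_df.to_csv(out / "sizes.csv", index=False, float_format="%.10g")
            report["stages"]["sizes"] = {
                "scales": config.compare_scales,
                "n_significant": int(sizes_df["significant"].sum()),
            }

        # --- dimensionality on the peak trained layer ----------------------
        stage = "dimensionality"
        peak_layer = trained[peak]
        sub = subsample_similarity(peak_layer, neural_rdm, config.fractions,
                                   n_samples=config.n_subsample,
                                   seed=child_seed(config.seed, "subsample"))
        pd.DataFrame(dict(fraction=sub.fractions, unit_count=sub.unit_counts,
                          median_rho=sub.median_rho, lo_rho=sub.lo_rho,
                          hi_rho=sub.hi_rho)).to_csv(
            out / "subsample.csv", index=False, float_format="%.10g")
        n_diff = filter_differential_units(peak_layer).n_units
        max_k = min(config.max_k, n_diff, pixel_rdm.n_stimuli - 1)
        pca = pca_similarity_curve(peak_layer, neural_rdm, max_k)
        pd.DataFrame(dict(k=pca.k_values, rho=pca.rho_per_k,
                          cumulative_explained_variance=pca.cumulative_explained_variance)
                     ).to_csv(out / "pca_curve.csv", index=False, float_format="%.10g")
        report["stages"]["dimensionality"] = {
            "peak_layer": peak + 1,
            "subsample_median_rho": sub.median_rho,
            "pca_rho_final": pca.rho_per_k[-1],
            "explained_variance_final": pca.cumulative_explained_variance[-1],
        }

        # --- group profiles and contrasts ----------------------------------
        stage = "contrasts"
        sorting = simulate_sorting(
            make_sorting_probabilities(shape_set.ids())[0],
            n_subjects=gen.n_subjects, seed=child_seed(config.seed, "sorting"),
            stimulus_ids=shape_set.ids())
        human = human_profile_from_rdm(sorting.to_rdm())
        neural_profile = group_pair_distances(neural_rdm, source_tag="neurons")
        pixel_profile = group_pair_distances(pixel_rdm, source_tag="pixels")
        profiles = {"neurons": neural_profile, "pixels": pixel_profile}
        for k, r in enumerate(trained_rdms):
            profiles[f"trained-{k + 1}"] = group_pair_distances(r, source_tag=r.layer_id)
        for k, r in enumerate(untrained_rdms):
            profiles[f"untrained-{k + 1}"] = group_pair_distances(r, source_tag=r.layer_id)
        prof_rows = []
        for tag, p in profiles.items():
            for ci, cname in enumerate(("R", "IC", "ISC", "ISS", "ISCa_vs_ISSa",
                                        "ISCb_vs_ISSb")):
                prof_rows.append(dict(source=tag, contrast=cname,
                                      mean=p.means[ci], sem=p.sems[ci], n=8))
        pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False,
                                       float_format="%.10g")
        corr_rows = []
        for k in range(gen.n_layers):
            for variant in ("trained", "untrained"):
                p = profiles[f"{variant}-{k + 1}"]
                corr_rows.append(dict(
                    layer=k + 1, variant=variant,
                    r_neural=profile_correlation(p, neural_profile, "neural_6"),
                    r_human=profile_correlation(p, human, "human_5"),
                    curved_straight_p=curved_straight_test(p),
                ))
        corr_df = pd.DataFrame(corr_rows)
        corr_df.to_csv(out / "profile_correlations.csv", index=False,
                       float_format="%.10g")
        deep_tr = corr_df[(corr_df.layer == gen.n_layers) & (corr_df.variant == "trained")]
        report["stages"]["contrasts"] = {
            "neural_profile_r_peak_trained": float(
                corr_df[(corr_df.layer == peak + 1) & (corr_df.variant == "trained")]
                .r_neural.iloc[0]),
            "human_profile_r_deepest_trained": float(deep_tr.r_human.iloc[0]),
            "curved_straight_p_deepest_trained": float(deep_tr.curved_straight_p.iloc[0]),
        }

        report["ok"] = True
        with open(out / "report.json", "w") as f:
            json.dump(report, f, indent=1, sort_keys=True)
        return report
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed (config {chash}): {e}") from e


def compare_sizes(config: AnalysisConfig, scale_factors,
                  _dataset=None, _profile=None) -> pd.DataFrame:
    """Layer-wise RSA at several stimulus scales with paired tests per layer.

    Stimuli are regenerated per scale factor (same seed), the surrogate layer
    stack is rebuilt on each scale's pixel geometry, and one bootstrap call
    shares the neural unit resamples across every (layer, scale) cell, so the
    per-layer difference between the first and each subsequent scale is a
    paired test; FDR is applied within the family of layers per comparison.
    """
    scales = list(scale_factors)
    if len(scales) < 2:
        raise ValueError("need at least 2 scale factors")
    gen = config.generator
    units = gen.units()
    mixing = _trained_mixing(gen.n_layers)

    per_scale_rdms = []
    shape_sets = {}
    for s in scales:
        scfg = config.stimulus.to_stimulus_config(scale=s)
        ss = shape_sets.get(s) or build_shape_set(scfg, seed=child_seed(config.seed, "stimuli"))
        shape_sets[s] = ss
        pix = pixel_features(ss.images(), ss.ids())
        profile = _profile if _profile is not None else _build_target(
            config, ss, compute_rdm(pix, "normalized_euclidean"))
        layers = simulate_layer_stack(pix, profile.target_rdm, gen.n_layers, units,
                                      mixing, redundancy=gen.redundancy,
                                      seed=child_seed(config.seed, "layers"))
        rdms = _layer_rdms(layers, config.metric)
        for k, r in enumerate(rdms):
            r.layer_id = f"layer{k + 1}@scale{s}"
        per_scale_rdms.append(rdms)

    dataset = _dataset
    if dataset is None:
        profile0 = _build_target(config, shape_sets[scales[0]],
                                 compute_rdm(pixel_features(
                                     shape_sets[scales[0]].images(),
                                     shape_sets[scales[0]].ids()),
                                     "normalized_euclidean"))
        dataset = simulate_neurons(
            shape_sets[scales[0]].ids(), profile0, n_units=gen.n_units,
            trials={"min": gen.trials_min, "median": gen.trials_median},
            noise_scale=gen.noise_scale, seed=child_seed(config.seed, "neurons"))
        dataset = screen_selective_units(dataset)

    flat = [r for rdms in per_scale_rdms for r in rdms]
    results = bootstrap_rsa(dataset, flat, metric=config.metric,
                            n_boot=config.n_boot,
                            seed=child_seed(config.seed, "bootstrap"))
    by_scale = [results[i * gen.n_layers:(i + 1) * gen.n_layers]
                for i in range(len(scales))]

    rows = []
    for si in range(1, len(scales)):
        pvals = [paired_bootstrap_test(by_scale[0][k], by_scale[si][k]).p
                 for k in range(gen.n_layers)]
        sig, qvals = fdr_correct(pvals, q_level=config.q_level)
        for k in range(gen.n_layers):
            rows.append(dict(layer=k + 1, scale=scales[si],
                             rho=by_scale[si][k].rho,
                             ci_low=by_scale[si][k].ci_low,
                             ci_high=by_scale[si][k].ci_high,
                             rho_reference_scale=by_scale[0][k].rho,
                             p_vs_reference=pvals[k], q=qvals[k],
                             significant=bool(sig[k])))
    for k in range(gen.n_layers):
        rows.insert(k, dict(layer=k + 1, scale=scales[0], rho=by_scale[0][k].rho,
                            ci_low=by_scale[0][k].ci_low,
                            ci_high=by_scale[0][k].ci_high,
                            rho_reference_scale=by_scale[0][k].rho,
                            p_vs_reference=np.nan, q=np.nan, significant=False))
    return pd.DataFrame(rows)
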