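"""Known-answer validation experiments over the synthetic-data generator.

Each function plants ground truth with :mod:`ctvtreg.synthetic_data`, runs
the corresponding analysis stage from scratch, and measures how well the
stage recovers the truth: false-discovery calibration under the null, planted
effect-size recovery, temporal-class recovery, the core-signature chain,
interaction-test type-I error, methylome bin arithmetic against a per-base
oracle, end-to-end demethylation detection, and origin-call accuracy.

Problem sizes are desk scale (a few thousand genes, a handful of dogs) so the
whole battery runs in about a minute; the same functions back both the test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .count_model import call_significant, fit_contrasts
from .methylome_profile import (
    MethylationTrack,
    baseline_subtract,
    bin_feature,
    demethylation_scores,
    derive_feature_regions,
    mean_signal,
    metagene_profile,
)
from .origin_assignment import assign_origin, assign_origins
from .synthetic_data import (
    SimulationConfig,
    simulate_counts,
    simulate_gene_models,
    simulate_methylation,
    simulate_variant_pileups,
)
from .temporal_signature import classify_temporal, core_signature

__all__ = [
    "fdr_null_calibration",
    "effect_recovery",
    "temporal_recovery",
    "core_signature_recovery",
    "interaction_type_i_error",
    "methylome_oracle_check",
    "methylome_end_to_end",
    "origin_benchmark",
]

_HIGH_EXPR = (float(np.log(100.0)), float(np.log(1000.0)))


def fdr_null_calibration(n_replicates: int = 20, n_genes: int = 2000, seed: int = 0) -> dict:
    """Mean false-discovery proportion of the full DE stage on null data.

    2,000 genes with no planted effects, 3 dogs x 2 biopsies, dispersion 0.05;
    discoveries at BH-adjusted p < 0.01 are all false by construction, so the
    per-replicate FDP is n_false / max(n_discoveries, 1).
    """
    fdps = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=n_genes, n_dogs_regressive=3, n_dogs_nonregressive=0,
            biopsies_per_dog=2, frac_early=0, frac_late=0, frac_progressive=0,
            frac_non_expressed=0, dispersion=0.05, seed=seed + rep,
        )
        cm, design, _ = simulate_counts(cfg)
        res = fit_contrasts(cm, design, "paired")["S_vs_P"].tested()
        n_disc = int((res["padj"] < 0.01).sum())
        fdps.append(n_disc / max(n_disc, 1))
    return {"mean_fdp": float(np.mean(fdps)), "n_replicates": n_replicates, "n_genes": n_genes}


def effect_recovery(seed: int = 0, n_genes: int = 2000) -> dict:
    """Sensitivity and estimate accuracy for planted 16-fold genes.

    6 regressive dogs x 2 biopsies, baselines in [100, 1000] so every planted
    gene sits at mu >= 100; called at FC > 10, adj-p < 0.01.
    """
    cfg = SimulationConfig(
        n_genes=n_genes, n_dogs_regressive=6, n_dogs_nonregressive=0,
        biopsies_per_dog=2, baseline_log_mean_range=_HIGH_EXPR,
        frac_early=0.1, frac_late=0, frac_progressive=0, frac_non_expressed=0,
        planted_log2fc=4.0, seed=seed,
    )
    cm, design, truth = simulate_counts(cfg)
    res = fit_contrasts(cm, design, "paired", filter_quantile=None)["S_vs_P"]
    called = call_significant(res)
    planted = truth.genes.index[truth.genes["true_class"] != "NONE"]
    sensitivity = float(np.mean([g in called for g in planted]))
    est = res.table.loc[planted, "log2fc"].abs()
    return {
        "sensitivity": sensitivity,
        "frac_within_half_log2": float(np.mean(np.abs(est - 4.0) <= 0.5)),
        "mean_abs_error_log2": float(np.mean(np.abs(est - 4.0))),
        "n_planted": int(len(planted)),
    }


def temporal_recovery(seed: int = 0, n_genes: int = 2000) -> dict:
    """Planted early/late/progressive label recovery on the 3-biopsy design."""
    cfg = SimulationConfig(
        n_genes=n_genes, n_dogs_regressive=3, n_dogs_nonregressive=0,
        biopsies_per_dog=3, baseline_log_mean_range=_HIGH_EXPR,
        frac_early=0.05, frac_late=0.05, frac_progressive=0.05,
        frac_non_expressed=0, seed=seed,
    )
    cm, design, truth = simulate_counts(cfg)
    results = fit_contrasts(cm, design, "paired", filter_quantile=None)
    sig = {name: call_significant(results[name]) for name in ("S_vs_P", "R_vs_S", "R_vs_P")}
    classes = classify_temporal(sig["S_vs_P"], sig["R_vs_S"], sig["R_vs_P"], universe=cm.genes)
    truth_cls = truth.genes["true_class"]
    planted = truth_cls.index[truth_cls != "NONE"]
    nulls = truth_cls.index[truth_cls == "NONE"]
    correct = float(np.mean([classes.loc[g, "label"] == truth_cls[g] for g in planted]))
    null_rate = float(np.mean([classes.loc[g, "label"] != "NONE" for g in nulls]))
    early = set(classes.index[classes["label"].str.startswith("EARLY")])
    late = set(classes.index[classes["label"].str.startswith("LATE")])
    prog = set(classes.index[classes["label"].str.startswith("PROG")])
    disjoint = not (early & late or early & prog or late & prog)
    return {
        "planted_label_recovery": correct,
        "null_label_rate": null_rate,
        "classes_disjoint": bool(disjoint),
        "n_planted": int(len(planted)),
    }


def core_signature_recovery(seed: int = 0, n_genes: int = 2000) -> dict:
    """Precision/recall of the full candidate -> core signature chain.

    Regression-specific (early, regressive-arm-only) genes are planted once
    and shared across three simulated datasets: the two-arm validation cohort
    (3+3 dogs, 2 biopsies) supplying the B2/B1 calls and the interaction
    test, a regressing index case and a non-regressing index case (2 dogs,
    3 biopsies each).
    """
    base = SimulationConfig(
        n_genes=n_genes, n_dogs_regressive=3, n_dogs_nonregressive=3,
        biopsies_per_dog=2, baseline_log_mean_range=_HIGH_EXPR,
        frac_early=0.05, frac_late=0, frac_progressive=0, frac_non_expressed=0,
        seed=seed,
    )
    cm2, des2, truth = simulate_counts(base)
    labels = truth.genes["true_class"].to_numpy()
    res2 = fit_contrasts(cm2, des2, "interaction", filter_quantile=None)
    sig_7xx = call_significant(res2["R_B2_vs_B1"])
    inter = res2["interaction"].tested()
    sig_inter = set(inter.index[inter["p"] < 0.05])

    c5_cfg = replace(base, n_dogs_regressive=2, n_dogs_nonregressive=0,
                     biopsies_per_dog=3, seed=seed + 1)
    cm5, des5, _ = simulate_counts(c5_cfg, planted_classes=labels)
    sig_c5 = call_significant(fit_contrasts(cm5, des5, "paired", filter_quantile=None)["R_vs_P"])
    c6_cfg = replace(base, n_dogs_regressive=0, n_dogs_nonregressive=2,
                     biopsies_per_dog=3, seed=seed + 2)
    cm6, des6, _ = simulate_counts(c6_cfg, planted_classes=labels)
    sig_c6 = call_significant(fit_contrasts(cm6, des6, "paired", filter_quantile=None)["R_vs_P"])

    sets = core_signature(sig_7xx, sig_inter, sig_c5, sig_c6)
    planted = set(truth.genes.index[truth.genes["true_class"] != "NONE"])
    core = set(sets.core)
    return {
        "precision": float(len(core & planted) / max(len(core), 1)),
        "recall": float(len(core & planted) / len(planted)),
        "core_size": len(core),
        "n_planted": len(planted),
    }


def interaction_type_i_error(n_replicates: int = 20, seed: int = 0, n_genes: int = 2000) -> dict:
    """Empirical type-I error of the interaction test at p < 0.05.

    The same time effect is planted in both arms, so every gene is null for
    the regression-status : time interaction.
    """
    rates = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=n_genes, n_dogs_regressive=3, n_dogs_nonregressive=3,
            biopsies_per_dog=2, frac_early=0.1, frac_late=0, frac_progressive=0,
            frac_non_expressed=0, time_effect_both_arms=True, seed=seed + rep,
        )
        cm, design, _ = simulate_counts(cfg)
        res = fit_contrasts(cm, design, "interaction")["interaction"].tested()
        rates.append(float((res["p"] < 0.05).mean()))
    return {"type_i_error": float(np.mean(rates)), "n_replicates": n_replicates}


def _per_base_mean(starts, ends, values, a: float, b: float) -> float:
    """Brute-force oracle: accumulate the step signal base by base."""
    total = 0.0
    for i in range(int(np.floor(a)), int(np.ceil(b))):
        lo, hi = max(a, float(i)), min(b, float(i + 1))
        if hi <= lo:
            continue
        v = 0.0
        for s, e, val in zip(starts, ends, values):
            if s <= i < e:
                v = val
                break
        total += v * (hi - lo)
    return total / (b - a)


def methylome_oracle_check(n_tracks: int = 200, n_genes: int = 50, seed: int = 0) -> dict:
    """Bin arithmetic against independent oracles.

    (1) mean_signal vs per-base accumulation on random step tracks;
    (2) conservation: the length-weighted mean of the 20 bins equals the
    feature-wide mean; (3) strand symmetry: reflecting a gene and its track
    through a pivot and flipping strand leaves the 140-vector unchanged.
    """
    rng = np.random.default_rng(seed)
    max_delta = 0.0
    for _ in range(n_tracks):
        bp = np.sort(rng.choice(np.arange(0, 500), size=10, replace=False)).astype(float)
        starts, ends = bp[:-1], bp[1:]
        values = rng.uniform(0, 5, size=len(starts))
        track = MethylationTrack({"c": (starts, ends, values)})
        lo = float(rng.integers(0, 200))
        length = float(rng.integers(15, 250))
        bins = bin_feature([(lo, lo + length)], "+", 20)
        got = mean_signal(track, bins, "c")
        want = np.array([_per_base_mean(starts, ends, values, a, b) for [(a, b)] in bins])
        max_delta = max(max_delta, float(np.max(np.abs(got - want))))

    conservation_err = 0.0
    for _ in range(50):
        bp = np.arange(0.0, 600.0, 13.0)
        track = MethylationTrack({"c": (bp[:-1], bp[1:], rng.uniform(0, 3, len(bp) - 2 + 1))})
        feature = [(31.0, 170.0), (200.0, 303.0)]
        bins = bin_feature(feature, "+", 20)
        means = mean_signal(track, bins, "c")
        total = sum(e - s for s, e in feature)
        fmean = sum(track.integral("c", s, e) for s, e in feature) / total
        conservation_err = max(conservation_err, abs(float(np.mean(means)) - fmean))

    models = simulate_gene_models(n_genes, seed=seed + 1)
    pivot = 1e7
    strand_delta = 0.0
    for m in models:
        span = m.span
        bp = np.arange(span[0] - 2500.0, span[1] + 2500.0, 41.0)
        vals = rng.uniform(0, 2, len(bp) - 1)
        track = MethylationTrack({m.chrom: (bp[:-1], bp[1:], vals)})
        prof = metagene_profile([derive_feature_regions(m)], {1: track}, normalize_tracks=False)
        from .methylome_profile import GeneModel

        refl_exons = sorted((int(pivot - e), int(pivot - s)) for s, e in m.exons)
        m2 = GeneModel(m.gene_id, m.chrom, "-" if m.strand == "+" else "+", refl_exons)
        s, e = bp[:-1], bp[1:]
        track2 = MethylationTrack({m.chrom: (pivot - e[::-1], pivot - s[::-1], vals[::-1])})
        prof2 = metagene_profile([derive_feature_regions(m2)], {1: track2}, normalize_tracks=False)
        d = np.nanmax(np.abs(prof.to_numpy() - prof2.to_numpy()))
        strand_delta = max(strand_delta, float(d))
    return {
        "oracle_max_abs_delta": max_delta,
        "conservation_max_err": conservation_err,
        "strand_reflection_max_delta": strand_delta,
        "n_tracks": n_tracks,
    }


def methylome_end_to_end(n_replicates: int = 20, n_genes: int = 60, seed: int = 0) -> dict:
    """Detection of planted first-exon demethylation across biopsies.

    Per replicate: plant a graded first-exon shift for the "early" list, run
    the full profile -> baseline-subtract -> score chain, and record whether
    the per-biopsy median demethylation score increases monotonically.  A
    non-planted feature (internal exons) is tracked as a negative control.
    """
    monotone = 0
    control_shifts = []
    for rep in range(n_replicates):
        models = simulate_gene_models(n_genes, seed=seed + rep)
        ids = [m.gene_id for m in models]
        third = n_genes // 3
        early, ne = ids[:third], ids[third : 2 * third]
        cfg = SimulationConfig(n_genes=n_genes, demeth_effect=0.1, meth_noise_sd=0.1,
                               seed=seed + rep)
        tracks, _ = simulate_methylation(models, {"early": early, "non_expressed": ne},
                                         cfg, n_biopsies=3)
        by_id = {m.gene_id: m for m in models}
        regions = [derive_feature_regions(by_id[g]) for g in early + ne]
        prof = metagene_profile(regions, tracks)
        ne_mask = prof.index.get_level_values("gene_id").isin(ne)
        normed = baseline_subtract(prof, prof[ne_mask])
        medians = []
        for b in (1, 2, 3):
            _, stats = demethylation_scores(normed, early, "first_exon", b)
            medians.append(stats["median"])
        monotone += medians[0] < medians[1] < medians[2]
        ctrl = []
        for b in (1, 3):
            try:
                _, stats = demethylation_scores(normed, early, "internal_exons", b)
                ctrl.append(stats["median"])
            except ValueError:
                ctrl = None
                break
        if ctrl is not None:
            control_shifts.append(ctrl[1] - ctrl[0])
    return {
        "frac_monotone": monotone / n_replicates,
        "control_feature_mean_shift": float(np.mean(control_shifts)) if control_shifts else 0.0,
        "n_replicates": n_replicates,
    }


def origin_benchmark(seed: int = 0, n_genes: int = 300) -> dict:
    """Origin-caller accuracy, single-site behaviour and allele-swap symmetry."""
    models = simulate_gene_models(n_genes, seed=seed)
    out: dict = {}
    for err, key in ((0.0, "accuracy_error0"), (0.01, "accuracy_error1pct")):
        cfg = SimulationConfig(n_genes=n_genes, allele_error_rate=err, seed=seed)
        _, piles, truth = simulate_variant_pileups(models, cfg)
        calls = assign_origins(piles)
        out[key] = float((calls["call"] == truth.loc[calls.index]).mean())
        if err == 0.01:
            swapped = piles.rename(columns={"tumor_count": "host_count",
                                            "host_count": "tumor_count"})
            flipped = assign_origins(swapped)
            flip = {"TUMOR": "HOST", "HOST": "TUMOR", "AMBIGUOUS": "AMBIGUOUS"}
            out["allele_swap_symmetric"] = bool(
                (flipped["call"] == calls["call"].map(flip)).all()
            )
    single_cfg = SimulationConfig(n_genes=n_genes, sites_per_transcript_range=(1, 1),
                                  allele_error_rate=0.0, seed=seed)
    _, piles1, _ = simulate_variant_pileups(models, single_cfg)
    calls1 = assign_origins(piles1)
    out["single_site_ambiguous_rate"] = float((calls1["call"] == "AMBIGUOUS").mean())
    out["n_genes"] = n_genes
    return out
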