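"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the regression-study design: a handful of dogs, two
or three serial tumour biopsies each, RNA-seq counts that are negative
binomial with gene-wise dispersion around a paired (dog-offset) mean model,
planted differentially expressed genes with early / late / progressive
trajectories confined to regressive dogs, methylation coverage tracks with
feature-localised demethylation trajectories, biallelic somatic sites that
tag each transcript as host- or tumour-derived, and qPCR Ct tables built
from a log-linear standard curve.

Everything is deterministic under the configured seed, and every planted
effect is recorded in a :class:`TruthTable` so downstream stages have a
known-answer surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .count_model import CountMatrix, SampleDesign, REGRESSIVE, NON_REGRESSIVE
from .methylome_profile import GeneModel, MethylationTrack, derive_feature_regions, FEATURES

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_gene_models",
    "simulate_counts",
    "simulate_methylation",
    "simulate_variant_pileups",
    "simulate_qpcr",
    "write_vcf",
]

CLASSES = ("EARLY_UP", "EARLY_DOWN", "LATE_UP", "LATE_DOWN", "PROG_UP", "PROG_DOWN")


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the regression study at desk scale: three regressive and
    three non-regressive dogs (the validation cohort had six), three biopsies
    for the time-course, NB counts with a bulk-RNA-seq-like dispersion of
    0.05, strong planted effects (log2FC = 4, i.e. 16-fold, comfortably past
    the 10-fold calling threshold), and a small fraction of genes per
    temporal class.
    """

    n_genes: int = 2000
    n_dogs_regressive: int = 3
    n_dogs_nonregressive: int = 3
    biopsies_per_dog: int = 3
    baseline_log_mean_range: tuple[float, float] = (np.log(20.0), np.log(2000.0))
    dispersion: float = 0.05
    dispersion_spread: float = 0.0  # lognormal sd of gene-wise alpha around `dispersion`
    frac_early: float = 0.05
    frac_late: float = 0.05
    frac_progressive: float = 0.05
    planted_log2fc: float = 4.0
    frac_non_expressed: float = 0.05
    frac_tumor_origin: float = 0.5
    sites_per_transcript_range: tuple[int, int] = (2, 6)
    depth_per_site_range: tuple[int, int] = (10, 60)
    allele_error_rate: float = 0.01
    demeth_effect: float = 0.1
    dog_offset_sd: float = 0.2
    time_effect_both_arms: bool = False
    meth_base_level: float = 1.0
    meth_noise_sd: float = 0.1
    meth_biopsy_noise_sd: float = 0.02
    meth_step: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.biopsies_per_dog not in (2, 3):
            raise ValueError("biopsies_per_dog must be 2 or 3")
        total = self.frac_early + self.frac_late + self.frac_progressive
        if total > 1 + 1e-12:
            raise ValueError("planted class fractions must sum to <= 1")
        for name in ("baseline_log_mean_range", "sites_per_transcript_range", "depth_per_site_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.allele_error_rate <= 1:
            raise ValueError("allele_error_rate must be a fraction")


@dataclass
class TruthTable:
    """Planted ground truth: per-gene classes/effects and per-sample factors."""

    genes: pd.DataFrame  # index gene_id: true_class, true_log2fc_b2, true_log2fc_b3
    size_factors: pd.Series  # per sample
    origins: pd.Series | None = None  # per gene: HOST | TUMOR
    demethylation: pd.DataFrame | None = None  # gene, feature, per-biopsy shift

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.reset_index().to_dict(orient="records"),
            "size_factors": self.size_factors.to_dict(),
        }
        if self.origins is not None:
            payload["origins"] = self.origins.to_dict()
        if self.demethylation is not None:
            payload["demethylation"] = self.demethylation.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(
    n_genes: int,
    seed: int,
    chrom: str = "chrS",
    max_exons: int = 10,
) -> list[GeneModel]:
    """Non-overlapping gene models on one synthetic chromosome.

    Each gene has 1-10 exons (lengths 40-400 bp), introns of 60-600 bp, a
    random strand, and at least 4 kb of intergenic gap so 2 kb flanks never
    collide.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    models = []
    cursor = 5000
    for i in range(n_genes):
        n_exons = int(rng.integers(1, max_exons + 1))
        exon_lens = rng.integers(40, 401, size=n_exons)
        intron_lens = rng.integers(60, 601, size=max(n_exons - 1, 0))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        models.append(GeneModel(f"gene{i:05d}", chrom, strand, exons))
        cursor = pos + 4000 + int(rng.integers(0, 4001))
    return models


# ---------------------------------------------------------------------------
# counts


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_genes
    counts = {
        "EARLY": round(cfg.frac_early * n),
        "LATE": round(cfg.frac_late * n),
        "PROG": round(cfg.frac_progressive * n),
    }
    labels = np.array(["NONE"] * n, dtype=object)
    perm = rng.permutation(n)
    pos = 0
    for cls, k in counts.items():
        chosen = perm[pos : pos + k]
        half = k // 2
        labels[chosen[:half]] = f"{cls}_DOWN"
        labels[chosen[half:]] = f"{cls}_UP"
        pos += k
    return labels


def _trajectory_log2(label: str, biopsy: int, fc: float) -> float:
    """Planted log2 shift relative to biopsy 1 for one temporal class."""
    if label == "NONE" or biopsy <= 1:
        return 0.0
    cls, direction = label.rsplit("_", 1)
    sign = 1.0 if direction == "UP" else -1.0
    if cls == "EARLY":
        shift = fc
    elif cls == "LATE":
        shift = fc if biopsy >= 3 else 0.0
    elif cls == "PROG":
        shift = fc / 2 if biopsy == 2 else fc
    else:
        raise ValueError(label)
    return sign * shift


def simulate_counts(
    config: SimulationConfig,
    planted_classes: np.ndarray | list[str] | None = None,
) -> tuple[CountMatrix, SampleDesign, TruthTable]:
    """NB counts over the paired multi-dog design with planted trajectories.

    Early genes shift by ``planted_log2fc`` (log2) at biopsies 2 and 3, late
    genes at biopsy 3 only, progressive genes by half at biopsy 2 and the
    full effect at biopsy 3; shifts apply only in regressive dogs (unless
    ``time_effect_both_arms``), so the regression-status : time interaction
    carries signal.  ``planted_classes`` overrides the random class
    assignment (one label per gene, from EARLY/LATE/PROG _UP/_DOWN or NONE),
    which lets several simulated datasets share their truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]

    if planted_classes is None:
        labels = _assign_classes(cfg, rng)
    else:
        labels = np.asarray(planted_classes, dtype=object)
        if len(labels) != cfg.n_genes:
            raise ValueError("planted_classes length must equal n_genes")
        bad = set(labels) - set(CLASSES) - {"NONE"}
        if bad:
            raise ValueError(f"unknown planted class labels: {sorted(bad)}")

    dogs = [(f"R{d+1}", REGRESSIVE) for d in range(cfg.n_dogs_regressive)] + [
        (f"N{d+1}", NON_REGRESSIVE) for d in range(cfg.n_dogs_nonregressive)
    ]
    if not dogs:
        raise ValueError("need at least one dog")
    rows = []
    for dog, status in dogs:
        for b in range(1, cfg.biopsies_per_dog + 1):
            rows.append({"sample_id": f"{dog}_B{b}", "dog": dog, "biopsy": b, "regression_status": status})
    sheet = pd.DataFrame(rows).set_index("sample_id")
    design = SampleDesign(sheet)

    # silent genes (zero expression everywhere) anchor the methylome baseline
    none_idx = np.flatnonzero(labels == "NONE")
    n_silent = min(round(cfg.frac_non_expressed * cfg.n_genes), len(none_idx))
    silent_idx = rng.choice(none_idx, size=n_silent, replace=False) if n_silent else np.array([], int)
    silent = np.zeros(cfg.n_genes, bool)
    silent[silent_idx] = True

    lo, hi = cfg.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=cfg.n_genes)
    dog_offsets = {dog: rng.normal(0.0, cfg.dog_offset_sd) for dog, _ in dogs}
    sf = rng.uniform(0.5, 2.0, size=len(sheet))
    if cfg.dispersion_spread > 0:
        alpha = cfg.dispersion * rng.lognormal(0.0, cfg.dispersion_spread, size=cfg.n_genes)
    else:
        alpha = np.full(cfg.n_genes, cfg.dispersion)

    ln2 = np.log(2.0)
    shift2 = np.array([_trajectory_log2(l, 2, cfg.planted_log2fc) for l in labels])
    shift3 = np.array([_trajectory_log2(l, 3, cfg.planted_log2fc) for l in labels])

    counts = np.empty((cfg.n_genes, len(sheet)), dtype=np.int64)
    for j, (sid, row) in enumerate(sheet.iterrows()):
        active = cfg.time_effect_both_arms or row["regression_status"] == REGRESSIVE
        shift = np.zeros(cfg.n_genes)
        if active:
            if row["biopsy"] == 2:
                shift = shift2
            elif row["biopsy"] == 3:
                shift = shift3
        mu = np.exp(baseline + dog_offsets[row["dog"]] + ln2 * shift) * sf[j]
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        counts[:, j] = np.where(silent, 0, rng.negative_binomial(n_param, p_param))

    cm = CountMatrix(genes, list(sheet.index), counts)
    max_b = cfg.biopsies_per_dog
    truth_genes = pd.DataFrame(
        {
            "true_class": labels,
            "true_log2fc_b2": shift2,
            "true_log2fc_b3": shift3 if max_b >= 3 else np.nan,
            "non_expressed": silent,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth = TruthTable(genes=truth_genes, size_factors=pd.Series(sf, index=sheet.index))
    return cm, design, truth


# ---------------------------------------------------------------------------
# methylation tracks


def _smooth_noise(rng: np.random.Generator, n: int, window: int = 9) -> np.ndarray:
    raw = rng.normal(0.0, 1.0, size=n + window - 1)
    kernel = np.ones(window) / window
    sm = np.convolve(raw, kernel, mode="valid")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def simulate_methylation(
    gene_models: list[GeneModel],
    gene_lists: dict[str, list[str]],
    config: SimulationConfig,
    target_feature: str = "first_exon",
    target_lists: tuple[str, ...] = ("early",),
    n_biopsies: int | None = None,
) -> tuple[dict[int, MethylationTrack], pd.DataFrame]:
    """Per-biopsy methylation coverage tracks with planted feature-local
    demethylation.

    The base signal is a smooth positive step track shared by all biopsies;
    each biopsy adds small independent noise.  For genes in the target
    list(s), the signal within ``target_feature`` is reduced by a graded
    shift — 0 at biopsy 1 rising linearly to ``demeth_effect`` at the last
    biopsy — so the planted demethylation trajectory is monotone in time.
    Non-expressed genes receive no shift.  Returns the tracks keyed by biopsy
    number and a truth table of planted per-biopsy shifts.
    """
    cfg = config
    if n_biopsies is None:
        n_biopsies = cfg.biopsies_per_dog
    if target_feature not in FEATURES:
        raise ValueError(f"unknown feature {target_feature!r}")
    known = {m.gene_id for m in gene_models}
    for name, ids in gene_lists.items():
        unknown = set(ids) - known
        if unknown:
            raise ValueError(f"gene list {name!r} contains unknown gene ids: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(cfg.seed + 101)
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in gene_models:
        by_chrom.setdefault(m.chrom, []).append(m)

    planted: list[tuple[str, str, float, float]] = []  # gene, chrom, start, end
    for lname in target_lists:
        for gid in gene_lists.get(lname, []):
            model = next(m for m in gene_models if m.gene_id == gid)
            fr = derive_feature_regions(model)
            if fr.present[target_feature]:
                for s, e in fr.regions[target_feature]:
                    planted.append((gid, model.chrom, s, e))

    step = cfg.meth_step
    tracks: dict[int, MethylationTrack] = {}
    base_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, models in by_chrom.items():
        span_end = max(m.span[1] for m in models) + 3000
        bp = np.arange(0, span_end + step, step, dtype=float)
        base = cfg.meth_base_level + cfg.meth_noise_sd * _smooth_noise(rng, len(bp) - 1)
        base_by_chrom[chrom] = (bp, base)

    truth_rows = []
    for b in range(1, n_biopsies + 1):
        frac = (b - 1) / max(n_biopsies - 1, 1)
        shift = cfg.demeth_effect * frac
        data = {}
        for chrom, (bp, base) in base_by_chrom.items():
            vals = base + cfg.meth_biopsy_noise_sd * _smooth_noise(rng, len(base))
            breaks = list(bp)
            values = list(vals)
            for gid, pchrom, s, e in planted:
                if pchrom != chrom or shift == 0:
                    continue
                breaks, values = _subtract_region(breaks, values, s, e, shift)
            starts = np.asarray(breaks[:-1])
            ends = np.asarray(breaks[1:])
            data[chrom] = (starts, ends, np.clip(np.asarray(values), 0.0, None))
        tracks[b] = MethylationTrack(data)
        for gid, _, _, _ in planted:
            truth_rows.append({"gene_id": gid, "feature": target_feature, "biopsy": b, "shift": shift})
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "feature", "biopsy", "shift"]).drop_duplicates()
    return tracks, truth


def _subtract_region(
    breaks: list[float], values: list[float], a: float, b: float, amount: float
) -> tuple[list[float], list[float]]:
    """Subtract ``amount`` from a piecewise-constant track over [a, b)."""
    import bisect

    def ensure_break(x: float) -> None:
        i = bisect.bisect_left(breaks, x)
        if i < len(breaks) and breaks[i] == x:
            return
        if 0 < i < len(breaks):  # splitting segment i-1
            breaks.insert(i, x)
            values.insert(i, values[i - 1])

    ensure_break(a)
    ensure_break(b)
    ia = bisect.bisect_left(breaks, a)
    ib = min(bisect.bisect_left(breaks, b), len(values))
    for i in range(ia, ib):
        values[i] -= amount
    return breaks, values


# ---------------------------------------------------------------------------
# variant pileups


def simulate_variant_pileups(
    gene_models: list[GeneModel],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Biallelic somatic sites and RNA allele counts with planted origins.

    Each gene draws k sites (``sites_per_transcript_range``) at exonic
    positions.  A TUMOR-origin gene emits the tumour allele at each site with
    probability 1 - ``allele_error_rate``; a HOST-origin gene emits the host
    allele at that rate.  Returns (sites, pileups, true origins).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 202)
    bases = np.array(list("ACGT"))
    site_rows, pile_rows, origins = [], [], {}
    k_lo, k_hi = cfg.sites_per_transcript_range
    d_lo, d_hi = cfg.depth_per_site_range
    for m in gene_models:
        origin = "TUMOR" if rng.random() < cfg.frac_tumor_origin else "HOST"
        origins[m.gene_id] = origin
        k = int(rng.integers(k_lo, k_hi + 1))
        exon_positions = np.concatenate([np.arange(s, e) for s, e in m.exons])
        k_eff = min(k, len(exon_positions))
        positions = np.sort(rng.choice(exon_positions, size=k_eff, replace=False))
        for pos in positions:
            host_allele, tumor_allele = rng.choice(bases, size=2, replace=False)
            depth = int(rng.integers(d_lo, d_hi + 1))
            p_tumor = (1 - cfg.allele_error_rate) if origin == "TUMOR" else cfg.allele_error_rate
            tumor_count = int(rng.binomial(depth, p_tumor))
            site_rows.append(
                {
                    "gene_id": m.gene_id,
                    "chrom": m.chrom,
                    "pos": int(pos),
                    "host_allele": host_allele,
                    "tumor_allele": tumor_allele,
                }
            )
            pile_rows.append(
                {
                    "gene_id": m.gene_id,
                    "pos": int(pos),
                    "depth": depth,
                    "tumor_count": tumor_count,
                    "host_count": depth - tumor_count,
                    "other_count": 0,
                }
            )
    sites = pd.DataFrame(site_rows)
    pileups = pd.DataFrame(pile_rows)
    return sites, pileups, pd.Series(origins, name="true_origin")


def write_vcf(sites: pd.DataFrame, path, chrom_length: int = 50_000_000) -> None:
    """Somatic sites as a minimal VCF: host allele in REF, tumour allele in ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom},length={chrom_length}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in sites.iterrows():
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.host_allele}\t{r.tumor_allele}\t.\tPASS\tGENE={r.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    standard_quantities: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001),
    slope: float = -1.0 / np.log10(2.0),
    intercept: float = 20.0,
    sigma: float = 0.0,
    n_replicates: int = 3,
    samples: dict[tuple[str, str], float] | None = None,
    target: str = "LINE-MYC",
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table for a dilution-series standard curve plus unknown samples.

    Ct = intercept + slope * log10(quantity) + N(0, sigma), emitted in
    triplicate (``n_replicates``).  The default slope, -1/log10(2) = -3.3219
    cycles per 10-fold dilution, corresponds to 100% amplification
    efficiency.  ``samples`` maps (target, sample_id) to a true relative
    quantity for unknown reactions.
    """
    if len(set(standard_quantities)) < 3:
        raise ValueError("need >= 3 distinct standard concentrations")
    if any(q <= 0 for q in standard_quantities):
        raise ValueError("standard quantities must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for q in standard_quantities:
        for rep in range(1, n_replicates + 1):
            ct = intercept + slope * np.log10(q) + (rng.normal(0, sigma) if sigma > 0 else 0.0)
            rows.append(
                {"target": target, "sample": f"std_{q:g}", "replicate": rep, "ct": ct,
                 "known_quantity": q, "role": "standard"}
            )
    if samples:
        for (tgt, sid), q in samples.items():
            if q <= 0:
                raise ValueError("sample quantities must be positive")
            for rep in range(1, n_replicates + 1):
                ct = intercept + slope * np.log10(q) + (rng.normal(0, sigma) if sigma > 0 else 0.0)
                rows.append(
                    {"target": tgt, "sample": sid, "replicate": rep, "ct": ct,
                     "known_quantity": np.nan, "role": "sample"}
                )
    return pd.DataFrame(rows)
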