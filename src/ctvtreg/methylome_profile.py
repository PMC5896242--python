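"""Feature-resolved meta-gene methylation profiling.

Each gene is decomposed into seven ordered feature regions — the 2 kb
upstream flank, first exon, first intron, internal exons, internal introns,
last exon and the 2 kb downstream flank, all in transcription order — and
each feature is split into 20 equal bins.  Mean methylation signal
(piecewise-constant coverage, e.g. MeDIP-seq depth from a bedGraph) is
computed per bin, the resulting 7 x 20 = 140-vector is profiled per biopsy,
and profiles are normalised by subtracting the per-bin mean over
non-expressed genes.  Gene lists are then summarised as per-feature,
per-biopsy demethylation-score boxplot statistics.

Coordinates are 0-based half-open internally; GTF input (1-based inclusive)
is converted on read, bedGraph is native.  Bins may have fractional-base
boundaries (features shorter than 20 bp still yield a rectangular grid);
means are length-weighted over the fractional extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "GeneModel",
    "FeatureRegions",
    "MethylationTrack",
    "derive_feature_regions",
    "bin_feature",
    "mean_signal",
    "metagene_profile",
    "baseline_subtract",
    "demethylation_scores",
    "define_non_expressed",
    "boxplot_stats",
    "read_gtf",
    "write_gtf",
]

FEATURES = (
    "upstream2kb",
    "first_exon",
    "first_intron",
    "internal_exons",
    "internal_introns",
    "last_exon",
    "downstream2kb",
)


@dataclass
class GeneModel:
    """Exon structure of one gene on one chromosome.

    Exons are (start, end) half-open 0-based intervals, non-overlapping and
    sorted by genomic position regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("a gene needs at least one exon")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError("empty exon interval")
            if s < prev_end:
                raise ValueError("overlapping exons")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


@dataclass
class FeatureRegions:
    """The seven ordered feature regions of a gene, in transcription order.

    ``regions`` maps feature name to a list of (start, end) genomic intervals
    ordered 5' to 3' along the transcript; absent features (single- or
    two-exon genes) map to an empty list and are flagged in ``present``.
    """

    gene_id: str
    chrom: str
    strand: str
    regions: dict[str, list[tuple[float, float]]]
    present: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.present:
            self.present = {f: bool(self.regions.get(f)) for f in FEATURES}


def derive_feature_regions(model: GeneModel, flank: int = 2000, chrom_length: int | None = None) -> FeatureRegions:
    """Decompose a gene into the seven feature regions, strand-aware.

    First/last exon are by transcription order; the first intron follows the
    first exon in transcription; internal exons/introns are everything in
    between.  Flanks extend up to ``flank`` bp beyond the transcript ends,
    clipped at the chromosome bounds.  A single-exon gene defines only the
    upstream flank, first exon (its only exon) and downstream flank; a
    two-exon gene additionally has a first intron and last exon but no
    internal features.
    """
    exons = list(model.exons)  # genomic order
    introns = model.introns
    minus = model.strand == "-"
    tx_exons = exons[::-1] if minus else exons
    tx_introns = introns[::-1] if minus else introns
    gstart, gend = model.span

    def clip(lo: float, hi: float) -> list[tuple[float, float]]:
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return [(lo, hi)] if hi > lo else []

    if minus:
        upstream = clip(gend, gend + flank)
        downstream = clip(gstart - flank, gstart)
    else:
        upstream = clip(gstart - flank, gstart)
        downstream = clip(gend, gend + flank)

    regions: dict[str, list[tuple[float, float]]] = {f: [] for f in FEATURES}
    regions["upstream2kb"] = upstream
    regions["downstream2kb"] = downstream
    regions["first_exon"] = [tx_exons[0]]
    if len(tx_exons) >= 2:
        regions["last_exon"] = [tx_exons[-1]]
        regions["first_intron"] = [tx_introns[0]]
    if len(tx_exons) >= 3:
        regions["internal_exons"] = list(tx_exons[1:-1])
        regions["internal_introns"] = list(tx_introns[1:])
    return FeatureRegions(model.gene_id, model.chrom, model.strand, regions)


def bin_feature(
    intervals: list[tuple[float, float]],
    strand: str,
    n_bins: int = 20,
) -> list[list[tuple[float, float]]]:
    """Split a feature (list of genomic intervals in transcription order) into
    ``n_bins`` equal-length bins along the concatenated transcript coordinate.

    Each returned bin is a list of genomic (start, end) sub-intervals (float
    boundaries; a bin may straddle an interval junction).  Bin 1 is 5'-most;
    on the minus strand bins run from high to low genomic coordinates.
    """
    if not intervals:
        raise ValueError("empty feature")
    lengths = [e - s for s, e in intervals]
    total = float(sum(lengths))
    if total <= 0:
        raise ValueError("feature has zero length")
    step = total / n_bins
    minus = strand == "-"
    bins: list[list[tuple[float, float]]] = []
    for b in range(n_bins):
        c0, c1 = b * step, (b + 1) * step
        parts: list[tuple[float, float]] = []
        offset = 0.0
        for (s, e), ln in zip(intervals, lengths):
            lo = max(c0, offset)
            hi = min(c1, offset + ln)
            if hi > lo:
                if minus:
                    # transcription runs e -> s within each interval
                    parts.append((e - (hi - offset), e - (lo - offset)))
                else:
                    parts.append((s + (lo - offset), s + (hi - offset)))
            offset += ln
        bins.append(parts)
    return bins


class MethylationTrack:
    """Piecewise-constant non-negative signal per chromosome.

    Backed by sorted, non-overlapping (start, end, value) arrays with a
    prefix-integral per chromosome, so the exact integral of the signal over
    any (possibly fractional) extent is an O(log n) query.  Uncovered extent
    contributes signal 0.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, float)
            ends = np.asarray(ends, float)
            values = np.asarray(values, float)
            order = np.argsort(starts)
            starts, ends, values = starts[order], ends[order], values[order]
            if (ends <= starts).any():
                raise ValueError("empty track interval")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError("overlapping track intervals")
            if not np.isfinite(values).all():
                raise ValueError("non-finite track values")
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._chroms[chrom] = (starts, ends, values, cum)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s, e, v, _ = self._chroms[chrom]
        return s, e, v

    def _prefix(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the signal over [min_coord, x)."""
        starts, ends, values, cum = self._chroms[chrom]
        x = np.asarray(x, float)
        j = np.searchsorted(starts, x, side="right") - 1
        jc = np.maximum(j, 0)
        inside = np.clip(x - starts[jc], 0.0, ends[jc] - starts[jc])
        return np.where(j >= 0, cum[jc] + values[jc] * inside, 0.0)

    def integral(self, chrom: str, a: float, b: float) -> float:
        if chrom not in self._chroms:
            return 0.0
        res = self._prefix(chrom, np.array([b])) - self._prefix(chrom, np.array([a]))
        return float(res[0])

    def mean(self, chrom: str, a: float, b: float) -> float:
        if b <= a:
            raise ValueError("empty extent")
        return self.integral(chrom, a, b) / (b - a)

    def total_mean(self) -> float:
        """Signal mass divided by covered genomic extent, over all chromosomes."""
        mass = 0.0
        length = 0.0
        for starts, ends, values, _ in self._chroms.values():
            mass += float(np.sum(values * (ends - starts)))
            length += float(np.sum(ends - starts))
        return mass / length if length else 0.0

    def scaled(self, factor: float) -> "MethylationTrack":
        return MethylationTrack(
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v, _) in self._chroms.items()}
        )

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, (starts, ends, values, _) in self._chroms.items():
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path) -> "MethylationTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
        )
        data = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            data[str(chrom)] = (
                sub["start"].to_numpy(float),
                sub["end"].to_numpy(float),
                sub["value"].to_numpy(float),
            )
        return cls(data)


def mean_signal(track: MethylationTrack, bins: list[list[tuple[float, float]]], chrom: str) -> np.ndarray:
    """Length-weighted mean signal per bin.

    Each bin is a list of (possibly fractional) genomic sub-intervals; the
    mean weights the piecewise-constant signal by overlap length, with
    uncovered extent contributing value 0 over its full length.
    """
    out = np.empty(len(bins))
    for i, parts in enumerate(bins):
        mass = 0.0
        length = 0.0
        for a, b in parts:
            mass += track.integral(chrom, a, b)
            length += b - a
        out[i] = mass / length if length > 0 else np.nan
    return out


def metagene_profile(
    feature_regions: list[FeatureRegions],
    tracks: dict[object, MethylationTrack],
    n_bins: int = 20,
    normalize_tracks: bool = True,
) -> pd.DataFrame:
    """Per-gene, per-biopsy 7 x ``n_bins`` methylation profile.

    Returns a DataFrame indexed by (gene_id, biopsy) with one column per
    (feature, bin); bins of absent features are NaN.  When
    ``normalize_tracks`` is set, each track is first scaled so its global
    mean signal is 1, removing between-sample coverage differences.
    """
    if not feature_regions:
        raise ValueError("empty gene list")
    cols = pd.MultiIndex.from_tuples(
        [(f, b + 1) for f in FEATURES for b in range(n_bins)], names=["feature", "bin"]
    )
    if normalize_tracks:
        tracks = {
            k: (t.scaled(1.0 / t.total_mean()) if t.total_mean() > 0 else t) for k, t in tracks.items()
        }
    rows = []
    index = []
    binned: dict[str, dict[str, list[list[tuple[float, float]]] | None]] = {}
    for fr in feature_regions:
        binned[fr.gene_id] = {
            f: (bin_feature(fr.regions[f], fr.strand, n_bins) if fr.present[f] else None)
            for f in FEATURES
        }
    for biopsy, track in tracks.items():
        for fr in feature_regions:
            vec = np.full(len(FEATURES) * n_bins, np.nan)
            for fi, f in enumerate(FEATURES):
                bins = binned[fr.gene_id][f]
                if bins is not None:
                    vec[fi * n_bins : (fi + 1) * n_bins] = mean_signal(track, bins, fr.chrom)
            rows.append(vec)
            index.append((fr.gene_id, biopsy))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["gene_id", "biopsy"]), columns=cols
    )


def baseline_subtract(
    profiles: pd.DataFrame,
    non_expressed_profiles: pd.DataFrame,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Subtract the per-biopsy, per-bin baseline over non-expressed genes.

    ``statistic`` is "mean" (default) or "median".
    """
    if non_expressed_profiles.empty:
        raise ValueError("empty non-expressed baseline set")
    agg = {"mean": "mean", "median": "median"}[statistic]
    baseline = non_expressed_profiles.groupby(level="biopsy").agg(agg)
    out = profiles.copy()
    for biopsy, base in baseline.iterrows():
        mask = out.index.get_level_values("biopsy") == biopsy
        out.loc[mask] = out.loc[mask] - base.to_numpy()[None, :]
    return out


def boxplot_stats(values: np.ndarray) -> dict[str, float]:
    """Median, quartiles (linear interpolation) and Tukey 1.5-IQR whiskers.

    Whiskers are the most extreme data points within 1.5 x IQR of the
    quartiles.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    in_lo = v[v >= lo_lim]
    in_hi = v[v <= hi_lim]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "lo_whisker": float(in_lo.min()) if in_lo.size else float(q1),
        "hi_whisker": float(in_hi.max()) if in_hi.size else float(q3),
    }


def demethylation_scores(
    normalized_profiles: pd.DataFrame,
    gene_list: list[str],
    feature: str,
    biopsy,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-gene demethylation score for one feature and biopsy, plus boxplot
    statistics over the gene list.

    The score is minus the mean of the feature's normalised bin values, so a
    gene less methylated than the non-expressed baseline scores positive
    (higher = more demethylated).  Genes lacking the feature are dropped.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    sel = normalized_profiles.loc[
        normalized_profiles.index.get_level_values("gene_id").isin(gene_list)
        & (normalized_profiles.index.get_level_values("biopsy") == biopsy)
    ]
    vals = sel[feature]
    scores = -vals.mean(axis=1, skipna=False)
    scores = scores.dropna()
    scores.index = scores.index.get_level_values("gene_id")
    if scores.empty:
        raise ValueError(f"no gene in the list has feature {feature!r}")
    return scores, boxplot_stats(scores.to_numpy())


def define_non_expressed(counts, sample_ids: list[str] | None = None) -> set[str]:
    """Genes with zero raw count in every scoped sample (strict-zero rule)."""
    df = counts.to_frame() if hasattr(counts, "to_frame") else pd.DataFrame(counts)
    if sample_ids is not None:
        df = df[sample_ids]
    return set(df.index[(df == 0).all(axis=1)])


# ---------------------------------------------------------------------------
# GTF I/O (1-based inclusive on disk, 0-based half-open in memory)


def write_gtf(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            gs, ge = m.span
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
            fh.write(
                f"{m.chrom}\tctvtreg\tgene\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tctvtreg\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes["gene_id"][0]
        rec = by_gene.setdefault(gid, {"chrom": exon.seqid, "strand": exon.strand, "exons": []})
        rec["exons"].append((exon.start - 1, exon.end))
    return [
        GeneModel(gid, rec["chrom"], rec["strand"], sorted(rec["exons"]))
        for gid, rec in by_gene.items()
    ]
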