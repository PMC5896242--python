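"""Host-vs-tumour transcript origin and qPCR tumour-burden quantification.

A transmissible tumour is genetically distinct from its host, so somatic
substitutions that distinguish the tumour genome from the host genome act as
origin markers: at a biallelic site, RNA reads carrying the tumour allele
come from tumour cells and reads carrying the host allele from host cells.
A transcript is called HOST or TUMOR only when at least ``min_variants``
sufficiently covered sites vote unanimously; everything else is AMBIGUOUS.
Genes deleted or truncated in the tumour genome are a second, absolute class
of host markers.

Tumour DNA burden is quantified from qPCR Ct values through a log-linear
standard curve (Ct = slope * log10(quantity) + intercept), normalising each
target's inferred quantity to a reference gene (beta-actin in the study) and
comparing biopsies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantSite",
    "OriginCall",
    "StandardCurve",
    "assign_origin",
    "assign_origins",
    "host_marker_lookup",
    "load_marker_set",
    "fit_standard_curve",
    "relative_quantity",
    "normalize_to_reference",
    "burden_change",
    "average_triplicates",
    "read_vcf_sites",
]


@dataclass
class VariantSite:
    gene_id: str
    pos: int  # 0-based
    tumor_allele: str
    host_allele: str

    def __post_init__(self) -> None:
        if self.tumor_allele == self.host_allele:
            raise ValueError("tumor and host alleles must differ")


@dataclass
class OriginCall:
    gene_id: str
    call: str  # HOST | TUMOR | AMBIGUOUS
    n_informative: int
    mean_tumor_fraction: float


@dataclass
class StandardCurve:
    slope: float  # cycles per log10 quantity
    intercept: float  # cycles
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 10^(-1/slope) - 1 (1.0 = 100%)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def assign_origin(
    pileups: pd.DataFrame,
    gene_id: str | None = None,
    min_variants: int = 2,
    min_depth: int = 8,
    majority: float = 0.8,
) -> OriginCall:
    """Call one gene's transcript origin from its per-site allele counts.

    ``pileups`` rows need ``depth``, ``tumor_count`` and ``host_count``.  A
    site is informative iff depth >= ``min_depth``; an informative site votes
    TUMOR when its tumour-allele fraction is >= ``majority``, HOST when the
    host fraction is, and abstains otherwise.  The gene is called only when
    at least ``min_variants`` informative sites exist and every
    non-abstaining vote agrees; anything else — too few sites, all
    abstentions, or a split vote — is AMBIGUOUS.
    """
    if gene_id is None:
        ids = pileups["gene_id"].unique() if "gene_id" in pileups else ["?"]
        if len(ids) > 1:
            raise ValueError("pileups span multiple genes; pass gene_id or pre-group")
        gene_id = str(ids[0])
    if pileups.empty:
        return OriginCall(gene_id, "AMBIGUOUS", 0, float("nan"))
    depth = pileups["depth"].to_numpy(float)
    informative = depth >= min_depth
    n_inf = int(informative.sum())
    if n_inf == 0:
        return OriginCall(gene_id, "AMBIGUOUS", 0, float("nan"))
    t = pileups.loc[informative, "tumor_count"].to_numpy(float)
    h = pileups.loc[informative, "host_count"].to_numpy(float)
    d = depth[informative]
    tf = t / d
    hf = h / d
    mean_tf = float(tf.mean())
    votes = np.where(tf >= majority, "TUMOR", np.where(hf >= majority, "HOST", "ABSTAIN"))
    voting = votes[votes != "ABSTAIN"]
    if n_inf < min_variants or len(voting) == 0 or len(set(voting)) > 1:
        return OriginCall(gene_id, "AMBIGUOUS", n_inf, mean_tf)
    return OriginCall(gene_id, str(voting[0]), n_inf, mean_tf)


def assign_origins(
    pileups: pd.DataFrame,
    min_variants: int = 2,
    min_depth: int = 8,
    majority: float = 0.8,
) -> pd.DataFrame:
    """Vectorised :func:`assign_origin` over a gene_id-keyed pileup table."""
    rows = []
    for gid, sub in pileups.groupby("gene_id", sort=True):
        c = assign_origin(sub, gid, min_variants, min_depth, majority)
        rows.append(
            {"gene_id": c.gene_id, "call": c.call, "n_informative": c.n_informative,
             "mean_tumor_fraction": c.mean_tumor_fraction}
        )
    return pd.DataFrame(rows).set_index("gene_id")


def host_marker_lookup(gene_id: str, host_marker_set) -> bool:
    """True iff the gene is a host marker (deleted/truncated in the tumour)."""
    return gene_id in set(host_marker_set)


def load_marker_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_vcf_sites(path) -> pd.DataFrame:
    """Somatic sites from a VCF (REF = host allele, ALT = tumour allele)."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append(
                {
                    "gene_id": rec.info.get("GENE", "."),
                    "chrom": rec.chrom,
                    "pos": rec.pos - 1,
                    "host_allele": rec.ref,
                    "tumor_allele": rec.alts[0] if rec.alts else ".",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR standard-curve arithmetic


def fit_standard_curve(standards) -> StandardCurve:
    """Least-squares Ct = slope * log10(quantity) + intercept.

    ``standards`` is an iterable of (known_quantity, ct) pairs with at least
    three distinct positive quantities.
    """
    pts = [(float(q), float(ct)) for q, ct in standards]
    qs = np.array([q for q, _ in pts])
    cts = np.array([c for _, c in pts])
    if (qs <= 0).any():
        raise ValueError("standard quantities must be positive")
    if len(np.unique(qs)) < 3:
        raise ValueError("need >= 3 distinct standard quantities")
    fit = stats.linregress(np.log10(qs), cts)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2))


def relative_quantity(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: quantity = 10^((ct - intercept) / slope)."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def normalize_to_reference(q_target: float, q_ref: float) -> float:
    """Target quantity normalised to the reference gene (e.g. ACTB)."""
    if q_ref <= 0:
        raise ValueError("reference quantity must be positive")
    return q_target / q_ref


def burden_change(ratio_b2: float, ratio_b1: float) -> float | None:
    """Fraction of tumour DNA remaining at the second biopsy.

    Returns None when the baseline ratio is zero (undefined).
    """
    if ratio_b1 == 0:
        return None
    return ratio_b2 / ratio_b1


def average_triplicates(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean Ct per (target, sample) before curve inversion."""
    return (
        ct_table.groupby(["target", "sample"], sort=False)["ct"].mean().rename("mean_ct").reset_index()
    )
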