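"""Per-sample SNP/indel summaries from a multi-sample variant table.

The in-memory container is a plain :class:`pandas.DataFrame` ("site table")
with one row per biallelic variant record and the columns

    chrom, pos, ref, alt, vclass, impact, consequence,
    GT:<sample>, RD:<sample>, AD:<sample>      (one triple per sample)

where ``vclass`` is one of ``SNP``/``INS``/``DEL``/``MNP``, ``GT`` is a
diploid genotype string (``0/0``, ``0/1``, ``1/1`` or ``./.``), and RD/AD are
reference/alternate read depths.  Multiallelic VCF records are decomposed into
one row per alternate allele on ingest, so the transition+transversion and
heterozygous+homozygous bookkeeping identities hold exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")

MISSING_GT = "./."


def gt_col(sample: str) -> str:
    return f"GT:{sample}"


def rd_col(sample: str) -> str:
    return f"RD:{sample}"


def ad_col(sample: str) -> str:
    return f"AD:{sample}"


def site_table_samples(sites: pd.DataFrame) -> list[str]:
    """Sample names present in a site table, in column order."""
    return [c[3:] for c in sites.columns if c.startswith("GT:")]


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as ``transition`` or ``transversion``.

    Purine<->purine (A<->G) and pyrimidine<->pyrimidine (C<->T) changes are
    transitions; every purine<->pyrimidine change is a transversion.
    """
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"substitution alleles must be single A/C/G/T bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r})")
    if (ref in _PURINES) == (alt in _PURINES):
        return "transition"
    return "transversion"


def variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(alt) > len(ref):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    return "MNP"


def ti_tv_ratio(transitions: int, transversions: int, ndigits: int = 2) -> float:
    """Transition/transversion ratio, rounded half-up to ``ndigits`` decimals."""
    if transversions == 0:
        return float("nan")
    return round_half_up(transitions / transversions, ndigits)


@dataclass
class SampleVariantSummary:
    """Variant bookkeeping for one sample (parent or bulk).

    Only sites the sample actually carries (genotype 0/1 or 1/1) are counted,
    so ``het_count + hom_count == variant_count`` by construction.
    """

    sample: str
    variant_count: int = 0
    snp_count: int = 0
    transitions: int = 0
    transversions: int = 0
    het_count: int = 0
    hom_count: int = 0
    insertions: int = 0
    deletions: int = 0
    indel_lengths: Counter = field(default_factory=Counter)
    impact_counts: dict = field(default_factory=lambda: {k: 0 for k in IMPACT_CLASSES})
    unannotated: int = 0

    @property
    def ti_tv(self) -> float:
        return ti_tv_ratio(self.transitions, self.transversions)


def _carried_mask(sites: pd.DataFrame, sample: str) -> np.ndarray:
    col = gt_col(sample)
    if col not in sites.columns:
        raise KeyError(f"unknown sample {sample!r}; table has {site_table_samples(sites)}")
    gt = sites[col].to_numpy()
    return (gt == "0/1") | (gt == "1/0") | (gt == "1/1")


def sample_summary(sites: pd.DataFrame, sample: str) -> SampleVariantSummary:
    """Summarise one sample's variants: Ti/Tv, zygosity, indels, impact classes."""
    out = SampleVariantSummary(sample=sample)
    if len(sites) == 0:
        return out
    carried = _carried_mask(sites, sample)
    sub = sites.loc[carried]
    gt = sub[gt_col(sample)].to_numpy()
    out.variant_count = len(sub)
    out.het_count = int(((gt == "0/1") | (gt == "1/0")).sum())
    out.hom_count = int((gt == "1/1").sum())

    snps = sub.loc[sub["vclass"] == "SNP"]
    out.snp_count = len(snps)
    for ref, alt in zip(snps["ref"], snps["alt"]):
        if classify_substitution(ref, alt) == "transition":
            out.transitions += 1
        else:
            out.transversions += 1

    indels = sub.loc[sub["vclass"].isin(("INS", "DEL"))]
    lengths = (indels["alt"].str.len() - indels["ref"].str.len()).to_numpy()
    out.indel_lengths = Counter(int(v) for v in lengths)
    out.insertions = int((lengths > 0).sum())
    out.deletions = int((lengths < 0).sum())

    if "impact" in sub.columns:
        for label in sub["impact"]:
            if label is None or (isinstance(label, float) and np.isnan(label)) or label == "":
                out.unannotated += 1
            elif label in IMPACT_CLASSES:
                out.impact_counts[label] += 1
            else:
                raise ValueError(f"unrecognized impact label {label!r}")
    else:
        out.unannotated = len(sub)
    return out


def indel_length_spectrum(sites: pd.DataFrame, sample: str) -> dict[int, int]:
    """Signed-length histogram of the indels a sample carries.

    Insertions have positive length ``len(alt) - len(ref)``; deletions are
    negative.
    """
    return dict(sample_summary(sites, sample).indel_lengths)


def impact_tally(sites: pd.DataFrame, sample: str) -> dict[str, int]:
    """Counts of HIGH/MODERATE/LOW/MODIFIER annotations carried by a sample."""
    return dict(sample_summary(sites, sample).impact_counts)


def summary_table(sites: pd.DataFrame, samples: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-sample summary in the conventional report layout (one row per sample)."""
    samples = list(samples) if samples is not None else site_table_samples(sites)
    rows = []
    for s in samples:
        sm = sample_summary(sites, s)
        rows.append(
            {
                "sample": s,
                "variant_no": sm.variant_count,
                "snp_no": sm.snp_count,
                "transition": sm.transitions,
                "transversion": sm.transversions,
                "ti_tv": sm.ti_tv,
                "heterozygosity_no": sm.het_count,
                "homozygosity_no": sm.hom_count,
                "insertion_no": sm.insertions,
                "deletion_no": sm.deletions,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF ingest
# ---------------------------------------------------------------------------

def _gt_string(allele_a: int, allele_b: int, alt_index: int) -> str:
    """Genotype of one sample with respect to a single alternate allele.

    Alleles other than ``alt_index`` (from a decomposed multiallelic record)
    are treated as reference for this row.
    """
    if allele_a < 0 or allele_b < 0:
        return MISSING_GT
    a = 1 if allele_a == alt_index else 0
    b = 1 if allele_b == alt_index else 0
    return f"{min(a, b)}/{max(a, b)}"


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into a site table, decomposing multiallelic records.

    Requires per-sample GT and AD fields.  An ``IMPACT=`` INFO key or a
    SnpEff-style ``ANN=`` string (impact in the third ``|``-separated slot)
    populates the ``impact``/``consequence`` columns when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        genotypes = rec.genotypes  # [[a, b, phased], ...]
        impact = rec.INFO.get("IMPACT")
        consequence = rec.INFO.get("CSQ")
        ann = rec.INFO.get("ANN")
        if impact is None and ann:
            fields = str(ann).split(",")[0].split("|")
            if len(fields) > 2:
                consequence = consequence or fields[1]
                impact = fields[2]
        for k, alt in enumerate(rec.ALT):
            row = {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "vclass": variant_class(rec.REF, alt),
                "impact": impact,
                "consequence": consequence,
            }
            for j, s in enumerate(samples):
                a, b = genotypes[j][0], genotypes[j][1]
                row[gt_col(s)] = _gt_string(a, b, k + 1)
                if ad is not None and ad.shape[1] > k + 1:
                    rd_v, ad_v = int(ad[j][0]), int(ad[j][k + 1])
                    row[rd_col(s)] = max(rd_v, 0)
                    row[ad_col(s)] = max(ad_v, 0)
                else:
                    row[rd_col(s)] = 0
                    row[ad_col(s)] = 0
            rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "vclass", "impact", "consequence"]
    for s in samples:
        cols += [gt_col(s), rd_col(s), ad_col(s)]
    return pd.DataFrame(rows, columns=cols)


def write_vcf(sites: pd.DataFrame, path, contigs: Mapping[str, int] | None = None) -> None:
    """Write a site table as an uncompressed 4-column-FORMAT VCF (GT:AD:DP)."""
    samples = site_table_samples(sites)
    lines = ["##fileformat=VCFv4.2", "##source=bsascan"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Functional impact class">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence label">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for d in sites.to_dict("records"):
        info_parts = []
        if isinstance(d.get("impact"), str) and d["impact"]:
            info_parts.append(f"IMPACT={d['impact']}")
        if isinstance(d.get("consequence"), str) and d["consequence"]:
            info_parts.append(f"CSQ={d['consequence']}")
        info = ";".join(info_parts) or "."
        fields = [d["chrom"], str(d["pos"]), ".", d["ref"], d["alt"], ".", "PASS", info, "GT:AD:DP"]
        for s in samples:
            rd, ad = int(d[rd_col(s)]), int(d[ad_col(s)])
            fields.append(f"{d[gt_col(s)]}:{rd},{ad}:{rd + ad}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
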