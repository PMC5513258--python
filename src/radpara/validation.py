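"""Assay-style SNP classes A-G and in-silico vs assay genotype concordance.

A genotyped SNP is classified by the set of distinct genotype clusters it
shows across individuals: A = two homozygotes plus a heterozygote, B = one
homozygote plus a heterozygote, C = the two homozygotes, D = a single
homozygote (monomorphic), E = a heterozygote cluster only (the collapsed-
paralog signature), F = unreadable (too many failed entries), G = unamplified
(every entry failed).  Classes A-C count as validated SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VALIDATED_CLASSES = frozenset({"A", "B", "C"})
FAIL = "FAIL"

#: minimum fraction of readable (non-failed) entries before a SNP is "unreadable"
READABLE_THRESHOLD = 2.0 / 3.0


@dataclass
class SNPClass:
    snp_id: str
    snp_class: str  # A..G
    validated: bool


@dataclass
class ConcordanceReport:
    """Agreement between in-silico calls and assay genotypes.

    ``pct_match`` is computed over entries where both sides made a call;
    ``pct_missing_in_silico`` over assay-called entries.
    """

    pct_match: float
    pct_missing_in_silico: float
    n_compared: int
    per_individual: pd.DataFrame


def _is_missing(entry) -> bool:
    return (
        entry is None
        or (isinstance(entry, float) and np.isnan(entry))
        or entry in ("./.", "", "NA")
    )


def _canon_genotype(entry) -> str:
    return "".join(sorted(str(entry).upper()))


def assign_class(
    genotypes,
    snp_id: str = "",
    readable_threshold: float = READABLE_THRESHOLD,
) -> SNPClass:
    """Classify one SNP from its assay genotypes across individuals.

    ``genotypes`` holds two-letter genotype strings or ``"FAIL"`` entries.
    """
    entries = list(genotypes)
    if not entries:
        raise ValueError("need at least one individual")
    readable = [g for g in entries if not (_is_missing(g) or str(g).upper() == FAIL)]
    if not readable:
        return SNPClass(snp_id, "G", False)
    if len(readable) / len(entries) < readable_threshold:
        return SNPClass(snp_id, "F", False)
    clusters = {_canon_genotype(g) for g in readable}
    homs = {g for g in clusters if g[0] == g[1]}
    hets = clusters - homs
    if len(homs) == 2 and len(hets) == 1:
        cls = "A"
    elif len(homs) == 1 and len(hets) == 1:
        cls = "B"
    elif len(homs) == 2 and not hets:
        cls = "C"
    elif len(homs) == 1 and not hets:
        cls = "D"
    elif not homs and len(hets) == 1:
        cls = "E"
    else:
        # >= 2 heterozygote clusters or > 2 homozygotes: multiallelic patterns,
        # unreadable as a simple cluster plot
        cls = "F"
    return SNPClass(snp_id, cls, cls in VALIDATED_CLASSES)


def classify_assay_table(assay: pd.DataFrame) -> pd.DataFrame:
    """Class assignment for every SNP column of an individuals x SNPs table."""
    rows = [
        {"snp_id": snp, "snp_class": (c := assign_class(assay[snp], snp)).snp_class,
         "validated": c.validated}
        for snp in assay.columns
    ]
    return pd.DataFrame(rows, columns=["snp_id", "snp_class", "validated"])


def concordance(in_silico: pd.DataFrame, assay: pd.DataFrame) -> ConcordanceReport:
    """Compare two individuals x SNPs genotype tables over their shared index."""
    inds = in_silico.index.intersection(assay.index)
    snps = in_silico.columns.intersection(assay.columns)
    if len(inds) == 0 or len(snps) == 0:
        raise ValueError("no shared (individual, SNP) entries to compare")
    a = assay.loc[inds, snps]
    s = in_silico.loc[inds, snps]

    assay_called = a.map(lambda g: not (_is_missing(g) or str(g).upper() == FAIL))
    silico_called = s.map(lambda g: not _is_missing(g))
    both = assay_called & silico_called
    match = pd.DataFrame(
        np.where(
            both,
            a.map(lambda g: _canon_genotype(g) if not _is_missing(g) else "")
            == s.map(lambda g: _canon_genotype(g) if not _is_missing(g) else "x"),
            False,
        ),
        index=a.index,
        columns=a.columns,
    )

    per_ind = pd.DataFrame(
        {
            "n_assay_called": assay_called.sum(axis=1),
            "n_both_called": both.sum(axis=1),
            "n_match": match.sum(axis=1),
        }
    )
    per_ind["pct_match"] = 100.0 * per_ind.n_match / per_ind.n_both_called.replace(0, np.nan)
    per_ind["pct_missing_in_silico"] = 100.0 * (
        1.0 - both.sum(axis=1) / assay_called.sum(axis=1).replace(0, np.nan)
    )

    n_both = int(both.to_numpy().sum())
    n_assay = int(assay_called.to_numpy().sum())
    pct_match = 100.0 * match.to_numpy().sum() / n_both if n_both else float("nan")
    pct_missing = 100.0 * (1.0 - n_both / n_assay) if n_assay else float("nan")
    return ConcordanceReport(float(pct_match), float(pct_missing), n_both, per_ind)
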