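"""File formats: pileup-TSV, genotype matrices, FASTA references, VCF output.

The pileup-TSV dialect has a header line ``locus_id  pos  ref  <ind>_A
<ind>_C <ind>_G <ind>_T ...`` with one row per (locus, 0-based site) and four
non-negative integer count columns per individual.  Internal coordinates are
0-based throughout; VCF emission converts to 1-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import Locus, PileSet, validate_bases
from .likelihood import BASES


class PileFormatError(ValueError):
    """Malformed pileup-TSV input."""


def _individuals_from_header(columns) -> list[str]:
    if list(columns[:3]) != ["locus_id", "pos", "ref"]:
        raise PileFormatError(
            f"header must start with locus_id, pos, ref; got {list(columns[:3])}"
        )
    rest = list(columns[3:])
    if not rest or len(rest) % 4:
        raise PileFormatError(
            f"expected 4 count columns per individual, got {len(rest)} count columns"
        )
    individuals = []
    for i in range(0, len(rest), 4):
        block = rest[i : i + 4]
        names = {c.rsplit("_", 1)[0] for c in block}
        suffixes = [c.rsplit("_", 1)[1] if "_" in c else "" for c in block]
        if len(names) != 1 or suffixes != list(BASES):
            raise PileFormatError(
                f"count columns must come as <ind>_A,<ind>_C,<ind>_G,<ind>_T; got {block}"
            )
        individuals.append(block[0].rsplit("_", 1)[0])
    if len(set(individuals)) != len(individuals):
        raise PileFormatError("duplicate individual names in header")
    return individuals


def read_piles(path) -> PileSet:
    """Read a pileup-TSV file into a :class:`PileSet`.

    Raises :class:`PileFormatError` naming the offending line for malformed
    headers or rows, and for negative counts.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "ref": str})
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise PileFormatError(f"{path}: cannot parse pileup-TSV ({exc})") from exc
    individuals = _individuals_from_header(df.columns)
    count_cols = list(df.columns[3:])

    if df[count_cols].isna().any().any() or df["pos"].isna().any():
        line = int(df[df[count_cols].isna().any(axis=1) | df["pos"].isna()].index[0]) + 2
        raise PileFormatError(f"{path}: missing value on line {line}")
    counts_flat = df[count_cols].to_numpy()
    if not np.issubdtype(counts_flat.dtype, np.number) or np.any(
        counts_flat != np.floor(counts_flat)
    ):
        raise PileFormatError(f"{path}: counts must be integers")
    if np.any(counts_flat < 0):
        line = int(np.flatnonzero((counts_flat < 0).any(axis=1))[0]) + 2
        raise PileFormatError(f"{path}: negative count on line {line}")

    piles = PileSet(individuals=individuals)
    for locus_id, sub in df.groupby("locus_id", sort=False):
        pos = sub["pos"].to_numpy(dtype=int)
        if len(np.unique(pos)) != len(pos):
            raise PileFormatError(f"{path}: duplicate positions in locus {locus_id}")
        expect = np.arange(len(pos))
        if not np.array_equal(np.sort(pos), expect):
            raise PileFormatError(
                f"{path}: locus {locus_id} positions must cover 0..{len(pos) - 1}"
            )
        order = np.argsort(pos)
        ref = "".join(sub["ref"].to_numpy()[order])
        validate_bases(ref, f"locus {locus_id} reference")
        counts = (
            sub[count_cols]
            .to_numpy(dtype=np.int64)[order]
            .reshape(len(pos), len(individuals), 4)
        )
        piles.add_locus(Locus(str(locus_id), ref, counts))
    return piles


def write_piles(piles: PileSet, path) -> None:
    """Write a :class:`PileSet` as pileup-TSV (row order: locus, then position)."""
    cols = ["locus_id", "pos", "ref"] + [
        f"{ind}_{b}" for ind in piles.individuals for b in BASES
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for lid, locus in piles.loci.items():
            flat = locus.counts.reshape(locus.length, -1)
            for pos in range(locus.length):
                row = [lid, str(pos), locus.ref[pos]]
                row.extend(str(int(c)) for c in flat[pos])
                fh.write("\t".join(row) + "\n")


def write_genotype_matrix(calls: pd.DataFrame, path) -> None:
    """Genotype matrix TSV: rows ``locus:pos``, columns individuals, ``./.`` missing."""
    out = calls.fillna("./.")
    out.to_csv(path, sep="\t", index_label="site")


def read_genotype_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="site", dtype=str)
    return df.replace("./.", np.nan)


def read_assay_table(path) -> pd.DataFrame:
    """Assay genotype table TSV: rows individuals, columns SNP ids, FAIL entries."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def write_assay_table(assay: pd.DataFrame, path) -> None:
    assay.to_csv(path, sep="\t", index_label="individual")


def write_reference_fasta(references: dict[str, str], path) -> None:
    """One record per locus, locus id as header."""
    records = [
        SeqRecord(Seq(seq), id=lid, description="") for lid, seq in references.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_reference_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_vcf(
    snp_table: pd.DataFrame,
    references: dict[str, str],
    calls: pd.DataFrame,
    individuals: list[str],
    path,
) -> None:
    """Write SNPs as VCF 4.2 with PARA / LRTS / LRTP / MAF INFO keys.

    ``snp_table`` is one row per SNP (``locus_id``, ``pos``, ``alleles``,
    ``maf``, ``lrt_stat``, ``p_value``, ``flag``); ``calls`` is a site x
    individual genotype matrix indexed by ``locus:pos`` ("AG" strings, NaN
    missing).  POS is emitted 1-based; REF is the reference base at the site.
    """
    header = pysam.VariantHeader()
    for lid, seq in references.items():
        header.contigs.add(lid, length=len(seq))
    header.info.add("PARA", 0, "Flag", "Site flagged paralogous by the two-locus LRT")
    header.info.add("LRTS", 1, "Float", "Paralogy likelihood-ratio statistic")
    header.info.add("LRTP", 1, "Float", "Paralogy LRT p-value (chi-square df=1)")
    header.info.add("MAF", 1, "Float", "Minor allele frequency among called genotypes")
    header.formats.add("GT", 1, "String", "Genotype")
    for ind in individuals:
        header.add_sample(ind)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in snp_table.itertuples(index=False):
            lid, pos = row.locus_id, int(row.pos)
            if lid not in references:
                raise ValueError(f"SNP references unknown locus {lid}")
            ref_base = references[lid][pos]
            alleles = row.alleles.split("/")
            if ref_base not in alleles:
                raise ValueError(
                    f"{lid}:{pos}: reference base {ref_base} not among alleles {alleles}"
                )
            alts = [a for a in alleles if a != ref_base]
            rec = vcf.new_record(
                contig=lid, start=pos, alleles=tuple([ref_base] + alts)
            )
            if np.isfinite(row.lrt_stat):
                rec.info["LRTS"] = float(row.lrt_stat)
                rec.info["LRTP"] = float(row.p_value)
            if np.isfinite(row.maf):
                rec.info["MAF"] = float(row.maf)
            if row.flag == "PARA":
                rec.info["PARA"] = True
            allele_index = {a: i for i, a in enumerate([ref_base] + alts)}
            site_key = f"{lid}:{pos}"
            for ind in individuals:
                g = calls.loc[site_key, ind] if site_key in calls.index else None
                if g is None or (isinstance(g, float) and np.isnan(g)):
                    rec.samples[ind]["GT"] = (None, None)
                else:
                    g = str(g)
                    a1, a2 = g[0], g[1]
                    if a1 not in allele_index or a2 not in allele_index:
                        rec.samples[ind]["GT"] = (None, None)
                    else:
                        rec.samples[ind]["GT"] = (allele_index[a1], allele_index[a2])
            vcf.write(rec)


def load_config(path) -> dict:
    """Structured YAML config file -> plain dict (empty file -> empty dict)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def write_manifest(params: dict, path) -> None:
    """Run manifest: parameters plus package versions, as YAML text."""
    import scipy

    from . import __version__

    manifest = {
        "parameters": params,
        "versions": {
            "radpara": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
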