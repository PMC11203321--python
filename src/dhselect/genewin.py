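"""Candidate-gene retrieval around significant SNPs.

A gene is a candidate for a SNP when its body interval [start, end]
(1-based, inclusive) intersects the closed window [pos − w, pos + w], with
w = 10 kb by default.  A gene whose nearest edge is exactly w away is
therefore included; one at w + 1 bp is not.  Strand is reported but plays no
role in inclusion; upstream/downstream labels are genomic-coordinate
relative to the SNP (a gene entirely at lower coordinates is "upstream").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgument


@dataclass
class GeneModel:
    """One gene feature from a GFF3 annotation."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    description: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise InvalidArgument(f"gene {self.gene_id}: start > end")


def load_gff(path) -> list[GeneModel]:
    """Load gene features from a GFF3 file.

    Only ``gene``-type features are returned; descriptions come from the
    ``description``, ``Note`` or ``product`` attribute when present.  A file
    with no gene features yields an empty list with a warning.
    """
    import gffutils

    # light pre-validation so parse errors carry a line number
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {ln}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        desc = ""
        for key in ("description", "Note", "product"):
            if key in attrs:
                desc = attrs[key][0]
                break
        gid = attrs["ID"][0] if "ID" in attrs else feat.id
        genes.append(GeneModel(gid, str(feat.seqid), feat.start, feat.end,
                               feat.strand or "+", desc))
    if not genes:
        warnings.warn(f"{path}: no gene-type features found", stacklevel=2)
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.description:
                attrs += f";description={g.description}"
            fh.write(
                f"{g.chrom}\tdhselect\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def query_window(snps, genes: list[GeneModel], window: int = 10_000) -> pd.DataFrame:
    """Candidate genes within ``window`` bp of each significant SNP.

    ``snps`` is a DataFrame with columns (snp, chrom, pos) or a list of
    ``(snp_id, chrom, pos)`` tuples.  Returns one row per (SNP, gene) hit
    with the distance from the SNP to the nearest gene edge (0 when the SNP
    lies inside the gene body) and the relation (within/upstream/downstream).
    SNPs on chromosomes absent from the annotation are skipped with a warning.
    """
    if window < 0:
        raise InvalidArgument("window must be non-negative")
    if not isinstance(snps, pd.DataFrame):
        snps = pd.DataFrame(snps, columns=["snp", "chrom", "pos"])
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(str(g.chrom), []).append(g)
    rows = []
    for _, s in snps.iterrows():
        chrom, pos = str(s["chrom"]), int(s["pos"])
        if chrom not in by_chrom:
            warnings.warn(f"SNP {s['snp']}: chromosome {chrom!r} not in "
                          "annotation; skipped", stacklevel=2)
            continue
        for g in by_chrom[chrom]:
            if g.start <= pos + window and g.end >= pos - window:
                if g.start <= pos <= g.end:
                    dist, rel = 0, "within"
                elif g.end < pos:
                    dist, rel = pos - g.end, "upstream"
                else:
                    dist, rel = g.start - pos, "downstream"
                rows.append({
                    "snp": s["snp"], "chrom": chrom, "pos": pos,
                    "gene_id": g.gene_id, "start": g.start, "end": g.end,
                    "strand": g.strand, "distance": dist, "relation": rel,
                    "description": g.description,
                })
    return pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "gene_id", "start", "end",
                       "strand", "distance", "relation", "description"],
    )
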