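"""Readers and writers for the toolkit's interchange formats.

FASTA in/out goes through Biopython.  Genotypes travel as a long-format
CSV (``sample_id, locus, a1..a4``, blank = missing), the natural export
shape for capillary-electrophoresis fragment tables.  Matrices are
labeled square TSVs, trees Newick, SSR tables TSV, and BED6 export uses
0-based half-open coordinates.  All writers are deterministic byte for
byte; run provenance (parameters, versions, seed) is written separately.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import GenotypeTable
from .miner import SSRLocus

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genotypes",
    "write_genotypes",
    "read_coords",
    "read_primers",
    "read_lnp",
    "write_ssr_table",
    "write_bed",
    "write_matrix",
    "read_matrix",
    "write_newick",
    "write_provenance",
]


def read_fasta(path) -> dict[str, str]:
    """Ordered {id: sequence} from a (possibly line-wrapped) FASTA file;
    sequences are upper-cased, duplicate ids rejected."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path}: empty file")
        if not first.startswith(">"):
            raise ValueError(f"{path}: line 1: expected FASTA header '>'")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


GENOTYPE_HEADER = ["sample_id", "locus", "a1", "a2", "a3", "a4"]


def read_genotypes(path) -> GenotypeTable:
    """Long-format genotype CSV -> :class:`GenotypeTable`.

    Blank allele cells are missing; sizes must be positive integers and
    must fill from ``a1`` leftward (no gaps).  Errors name the row.
    """
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["sample_id", "locus"]:
            raise ValueError(f"{path}: expected header {GENOTYPE_HEADER}")
        for rownum, row in enumerate(reader, start=2):
            if not row or not any(c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: row {rownum}: too few fields")
            sample, locus = row[0].strip(), row[1].strip()
            raw = [c.strip() for c in row[2:6]]
            sizes = []
            seen_blank = False
            for c in raw:
                if c == "":
                    seen_blank = True
                    continue
                if seen_blank:
                    raise ValueError(
                        f"{path}: row {rownum}: allele after a blank slot"
                    )
                try:
                    v = int(c)
                except ValueError:
                    raise ValueError(
                        f"{path}: row {rownum}: non-integer size {c!r}"
                    ) from None
                if v <= 0:
                    raise ValueError(
                        f"{path}: row {rownum}: non-positive size {v}"
                    )
                sizes.append(v)
            records.append((sample, locus, tuple(sizes)))
    return GenotypeTable.from_records(records)


def write_genotypes(table: GenotypeTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(GENOTYPE_HEADER)
        for ind, loc, sizes in table.to_records():
            padded = list(sizes) + [""] * (4 - len(sizes))
            w.writerow([ind, loc, *padded])


def read_coords(path) -> pd.DataFrame:
    """Coordinates CSV (sample_id, lat, lon) indexed by sample_id."""
    df = pd.read_csv(path)
    if not {"sample_id", "lat", "lon"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, lat, lon")
    return df.set_index("sample_id")[["lat", "lon"]].astype(float)


def read_primers(path) -> list:
    """Primer panel CSV (name, forward, reverse[, dye, m13_tail])."""
    from .markers import PrimerPair

    df = pd.read_csv(path).fillna("")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PrimerPair(
                name=str(row["name"]),
                forward=str(row["forward"]).upper(),
                reverse=str(row["reverse"]).upper(),
                dye=str(row["dye"]) or None if "dye" in df.columns else None,
                m13_tail=bool(row.get("m13_tail", False))
                if "m13_tail" in df.columns
                else False,
            )
        )
    names = [p.name for p in pairs]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate primer names")
    return pairs


def read_lnp(path) -> pd.DataFrame:
    """LnP(K) replicate CSV with columns K, replicate, lnp."""
    df = pd.read_csv(path)
    if not {"K", "lnp"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns K, replicate, lnp")
    return df


SSR_COLUMNS = [
    "chrom", "start", "end", "motif", "canonical_motif", "unit_length",
    "n_repeats", "length_bp", "class", "compound_id",
]


def write_ssr_table(loci: Sequence[SSRLocus], path) -> None:
    rows = [
        {
            "chrom": l.chrom,
            "start": l.start,
            "end": l.end,
            "motif": l.motif,
            "canonical_motif": l.canonical,
            "unit_length": l.unit_length,
            "n_repeats": l.n_repeats,
            "length_bp": l.length_bp,
            "class": l.length_class,
            "compound_id": l.compound_id or "",
        }
        for l in loci
    ]
    pd.DataFrame(rows, columns=SSR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ssr_table(path) -> list[SSRLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    out = []
    for _, r in df.iterrows():
        cid = r.get("compound_id")
        cid = None if pd.isna(cid) or cid == "" else str(cid)
        out.append(
            SSRLocus(
                str(r["chrom"]), int(r["start"]), int(r["end"]),
                str(r["motif"]), int(r["unit_length"]), int(r["n_repeats"]),
                compound_id=cid,
            )
        )
    return out


def write_bed(loci: Sequence[SSRLocus], path) -> None:
    """BED6 export: 0-based half-open, name = motif xN, score = length."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.chrom}\t{l.start - 1}\t{l.end}\t"
                f"{l.motif}x{l.n_repeats}\t{l.length_bp}\t+\n"
            )


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_newick(newick: str, path) -> None:
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")


def write_provenance(outdir, seed, params: dict) -> Path:
    """Record run parameters, seed and library versions as JSON."""
    import numpy
    import scipy

    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = {
        "ssrkit": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "params": params,
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(doc, indent=2, default=str) + "\n")
    return path
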