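"""Readers and writers for the plain-text formats used throughout.

OTU tables are tab-separated: header row of sample ids, first column taxon
ids, remaining cells non-negative numbers.  Malformed files are rejected
with the offending line number.  Writers use canonical formatting (repr of
floats, integer-valued cells as integers) so read→write round-trips are
byte-stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityMatrix, SampleTable
from .profiles import DiversityProfile

__all__ = [
    "OtuTableError",
    "read_otu_table",
    "write_otu_table",
    "write_profiles",
    "write_dissimilarity",
]


class OtuTableError(ValueError):
    """Malformed OTU table, with the 1-based line number where possible."""


def _fmt(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def read_otu_table(path) -> SampleTable:
    """Parse a taxa × samples TSV into a :class:`SampleTable`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise OtuTableError("table needs a header row and at least one taxon row")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(sample_ids) == 0:
        raise OtuTableError("line 1: header has no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        raise OtuTableError("line 1: duplicate sample ids")
    ncol = len(header)
    taxa, rows = [], []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise OtuTableError(
                f"line {lineno}: expected {ncol} tab-separated fields, got {len(fields)}"
            )
        taxon = fields[0]
        if taxon in seen:
            raise OtuTableError(f"line {lineno}: duplicate taxon id {taxon!r}")
        seen.add(taxon)
        try:
            values = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise OtuTableError(f"line {lineno}: non-numeric abundance ({exc})") from exc
        bad = [v for v in values if not np.isfinite(v) or v < 0]
        if bad:
            raise OtuTableError(f"line {lineno}: negative or non-finite abundance {bad[0]}")
        taxa.append(taxon)
        rows.append(values)
    try:
        return SampleTable(taxa, sample_ids, np.array(rows))
    except ValueError as exc:
        raise OtuTableError(str(exc)) from exc


def write_otu_table(table: SampleTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(table.sample_ids) + "\n")
        for i, taxon in enumerate(table.taxon_ids):
            cells = "\t".join(_fmt(v) for v in table.matrix[i])
            fh.write(f"{taxon}\t{cells}\n")


def write_profiles(profiles, path) -> None:
    """Write one or more diversity profiles as a long-format TSV.

    Columns: sample, q, diversity, is_naive.  q = ∞ is written as ``inf``.
    """
    if isinstance(profiles, DiversityProfile):
        profiles = [profiles]
    rows = []
    for prof in profiles:
        for q, d in zip(prof.q_grid, prof.diversities):
            rows.append({
                "sample": prof.community_label,
                "q": q,
                "diversity": d,
                "is_naive": prof.is_naive,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dissimilarity(D: DissimilarityMatrix, path) -> None:
    D.to_frame().to_csv(path, sep="\t", index_label="sample")
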