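"""16S V6 ribotag extraction from shotgun reads.

Each read is scanned for an exact IUPAC match of the universal V6 primer
(CGACRRCCATGCANCACCT); the 33 nucleotides immediately downstream form the
tag, and each distinct tag is treated as one OTU.  Reads with fewer than
33 nt after the primer are discarded.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

from .synthio import V6_PRIMER, _IUPAC_CHOICES

__all__ = ["extract_v6_tags", "tags_to_otu_table", "V6_PRIMER"]

TAG_LENGTH = 33


def _primer_regex(primer: str) -> re.Pattern:
    parts = []
    for c in primer.upper():
        opts = _IUPAC_CHOICES.get(c)
        if opts is None:
            raise ValueError(f"invalid IUPAC code {c!r} in primer")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def extract_v6_tags(records: Iterable, primer: str = V6_PRIMER,
                    both_strands: bool = True) -> pd.DataFrame:
    """Scan reads for the primer and emit downstream 33-nt tags.

    The forward strand is scanned first; with ``both_strands`` the reverse
    complement is scanned when the forward strand has no usable match, and
    tags are reported in primer orientation.  The first usable match per
    read wins.  Returns a table (read_id, tag, strand).
    """
    pat = _primer_regex(primer)
    rows = []
    for rec in records:
        seq = str(rec.seq).upper()
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", str(Seq(seq).reverse_complement())))
        for strand, s in strands:
            hit = None
            for m in pat.finditer(s):
                end = m.end()
                if len(s) - end >= TAG_LENGTH:
                    hit = s[end:end + TAG_LENGTH]
                    break
            if hit is not None:
                rows.append((rec.id, hit, strand))
                break
    return pd.DataFrame(rows, columns=["read_id", "tag", "strand"])


def tags_to_otu_table(occurrences: pd.DataFrame,
                      read_samples: Mapping[str, str] | pd.Series,
                      metadata: pd.DataFrame) -> pd.DataFrame:
    """OTU table from tag occurrences.

    Rows are the distinct 33-mers in lexicographic order, columns are the
    samples of ``metadata`` (all of them, so empty samples keep zero
    columns), entries are occurrence counts.
    """
    samples = list(metadata.index)
    known = set(samples)
    counts: dict[str, dict[str, int]] = {}
    for rid, tag in zip(occurrences["read_id"], occurrences["tag"]):
        try:
            sid = read_samples[rid]
        except KeyError:
            raise KeyError(f"read {rid!r} has no sample assignment") from None
        if sid not in known:
            raise KeyError(f"read {rid!r} maps to unknown sample {sid!r}")
        counts.setdefault(tag, {}).setdefault(sid, 0)
        counts[tag][sid] += 1
    tags = sorted(counts)
    data = {s: [counts[t].get(s, 0) for t in tags] for s in samples}
    out = pd.DataFrame(data, index=pd.Index(tags, name="tag"), dtype=float)
    return out
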