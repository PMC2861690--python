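"""Readers and writers for the text formats the pipeline exchanges.

Genepop is the de-facto interchange format for diploid multiallelic
(microsatellite) data; FASTA carries mtDNA amplicons; CSV carries per-site
climate tables and per-individual trait tables.
"""

from __future__ import annotations

import io as _io
import re

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    CLIMATE_VARS,
    MISSING,
    PRECIP_VARS,
    FormatError,
    Genotypes,
    SiteTable,
)

_IUPAC = set("ACGTRYSWKMBDHVN")


# ---------------------------------------------------------------------------
# Genepop

def read_genepop(text: str) -> tuple[Genotypes, dict[str, str]]:
    """Parse Genepop text into :class:`Genotypes` plus a population map.

    Supports the 2- and 3-digit per-allele dialects (detected from the data),
    locus names one-per-line or comma-separated, and ``Pop`` delimiters
    (case-insensitive).  ``00``/``000`` encodes a missing allele copy.
    Populations are numbered ``pop_1 .. pop_N`` in file order.
    """
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) < 3:
        raise FormatError("truncated Genepop file")

    is_pop = lambda s: s.strip().lower() == "pop"

    # title, then locus names until the first Pop line
    loci: list[str] = []
    i = 1
    while i < len(lines) and not is_pop(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(t.strip() for t in chunk.split(",") if t.strip())
        i += 1
    if i >= len(lines):
        raise FormatError("no 'Pop' line found (zero populations)")
    if not loci:
        raise FormatError("no locus names before first 'Pop'")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop_idx = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if is_pop(line):
            pop_idx += 1
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise FormatError(f"line {lineno + 1}: expected 'label , genotypes'")
        label, _, geno = line.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise FormatError(
                f"line {lineno + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        calls = []
        for tok in tokens:
            if not re.fullmatch(r"\d+", tok) or len(tok) not in (4, 6):
                raise FormatError(f"line {lineno + 1}: bad genotype token {tok!r}")
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise FormatError(
                    f"line {lineno + 1}: allele width {w} != file width {width}"
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            calls.append((a1 if a1 else MISSING, a2 if a2 else MISSING))
        ids.append(label.strip())
        pops.append(f"pop_{pop_idx}")
        rows.append(calls)

    if pop_idx == 0:
        raise FormatError("zero populations")
    if not ids:
        raise FormatError("no individuals")

    # Genepop files commonly repeat the locality name as every label;
    # disambiguate so individual ids are unique keys.
    seen: dict[str, int] = {}
    uniq = []
    for label in ids:
        seen[label] = seen.get(label, 0) + 1
        uniq.append(label if seen[label] == 1 else f"{label}_{seen[label]}")

    pop_map = dict(zip(uniq, pops))
    gt = Genotypes(
        individual_ids=uniq,
        site_of=dict(pop_map),
        loci=loci,
        calls=np.array(rows, dtype=np.int64),
    )
    return gt, pop_map


def write_genepop(genotypes: Genotypes, pop_map: dict[str, str],
                  title: str = "contactzone export", digit_width: int = 3) -> str:
    """Serialize to Genepop text; byte-stable for identical input.

    Populations are emitted in order of first appearance over
    ``genotypes.individual_ids``; individuals keep their input order.
    """
    if digit_width not in (2, 3):
        raise ValueError("digit_width must be 2 or 3")
    if not pop_map:
        raise ValueError("empty population map")
    limit = 10 ** digit_width
    if (genotypes.calls >= limit).any():
        raise ValueError(f"allele code exceeds {digit_width}-digit encoding")

    order: dict[str, list[int]] = {}
    for idx, ind in enumerate(genotypes.individual_ids):
        order.setdefault(pop_map[ind], []).append(idx)

    out = [title]
    out.extend(genotypes.loci)
    for pop in order:
        out.append("Pop")
        for idx in order[pop]:
            toks = []
            for l in range(genotypes.n_loci):
                a1, a2 = genotypes.calls[idx, l]
                a1 = 0 if a1 == MISSING else int(a1)
                a2 = 0 if a2 == MISSING else int(a2)
                toks.append(f"{a1:0{digit_width}d}{a2:0{digit_width}d}")
            out.append(f"{genotypes.individual_ids[idx]} , " + " ".join(toks))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text; ids are the first token, sequences uppercased."""
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r}")
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(
                f"record {rec.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    if not records and text.strip():
        raise FormatError("no FASTA records parsed")
    return records


# ---------------------------------------------------------------------------
# Site / climate tables

def read_transect_table(text: str) -> SiteTable:
    """Parse a per-site CSV with transect, site, position and 19 climate columns.

    Row order defines site order unless the position column overrides it
    (sites are sorted by position per transect on access).
    """
    df = pd.read_csv(_io.StringIO(text))
    required = ["transect", "site", "position"] + CLIMATE_VARS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {missing}")
    if df.duplicated(subset=["transect", "site"]).any():
        dup = df[df.duplicated(subset=["transect", "site"])].iloc[0]
        raise FormatError(
            f"duplicate (transect, site) key: ({dup['transect']}, {dup['site']})"
        )
    vals = df[CLIMATE_VARS].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise FormatError("non-finite climate value")
    neg = df[PRECIP_VARS].lt(0)
    if neg.any().any():
        col = neg.any()[neg.any()].index[0]
        raise FormatError(f"negative precipitation value in column {col}")
    df = df.set_index(["transect", "site"])
    return SiteTable(frame=df)


def write_transect_table(table: SiteTable) -> str:
    return table.frame.reset_index().to_csv(index=False)


# ---------------------------------------------------------------------------
# Matrix export for clustering

def to_matrix(genotypes: Genotypes) -> pd.DataFrame:
    """Two-columns-per-locus individual matrix (missing = −9).

    One row per individual with its site index (order of first appearance)
    and a ``<locus>_1 / <locus>_2`` column pair per locus — the flat layout
    admixture-clustering programs consume.
    """
    site_index = {s: i + 1 for i, s in enumerate(genotypes.sites())}
    data: dict[str, list] = {
        "individual": list(genotypes.individual_ids),
        "site": [site_index[genotypes.site_of[i]] for i in genotypes.individual_ids],
    }
    calls = np.where(genotypes.calls == MISSING, -9, genotypes.calls)
    for l, locus in enumerate(genotypes.loci):
        data[f"{locus}_1"] = calls[:, l, 0].tolist()
        data[f"{locus}_2"] = calls[:, l, 1].tolist()
    return pd.DataFrame(data)
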