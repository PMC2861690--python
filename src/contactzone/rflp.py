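"""In-silico PCR-RFLP: restriction digest of mtDNA amplicons and lineage calls.

Cytochrome-b amplicons are classified into four maternal lineages by the
presence and position of SspI and DraI cut sites, mirroring how a gel-based
PCR-RFLP assay distinguishes haplogroups without sequencing every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import TransectDataset

#: IUPAC nucleotide classes for motif matching (sequence side must be ACGT)
_IUPAC_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition motif plus cut offset.

    ``cut_offset`` counts bases from the motif start to the cut (0-based);
    e.g. SspI AAT|ATT has offset 3.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError("motif length must be >= 4")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut offset outside motif")
        if any(ch not in _IUPAC_CLASS for ch in self.motif.upper()):
            raise ValueError(f"non-IUPAC motif {self.motif!r}")


#: canonical blunt cutters used by the default lineage assay
SSPI = EnzymeSpec("SspI", "AATATT", 3)
DRAI = EnzymeSpec("DraI", "TTTAAA", 3)


@dataclass
class DigestResult:
    """Outcome of digesting one linear sequence with one enzyme.

    ``cut_positions`` are 1-based indices of the last base 5' of each cut,
    ascending.  Fragment lengths always sum to the sequence length.
    """

    enzyme: str
    sequence_length: int
    cut_positions: list[int]
    fragment_lengths: list[int]


def digest(sequence: str, enzyme: EnzymeSpec) -> DigestResult:
    """Scan one strand of a linear sequence for enzyme motifs and cut.

    Overlapping motif occurrences are all reported.  IUPAC ambiguity is
    honoured in the motif only; an ambiguous base in the sequence never
    matches.  A motif longer than the sequence simply yields no cuts.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT characters {bad}")
    motif = enzyme.motif.upper()
    m = len(motif)
    cuts = []
    for s in range(len(seq) - m + 1):
        if all(seq[s + j] in _IUPAC_CLASS[motif[j]] for j in range(m)):
            pos = s + enzyme.cut_offset  # 1-based last base before the cut
            if 0 < pos < len(seq):
                cuts.append(pos)
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [len(seq)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    return DigestResult(enzyme.name, len(seq), cuts, fragments)


@dataclass(frozen=True)
class DigestPredicate:
    """One condition on a digest: a cut near ``position`` or no cut at all."""

    enzyme: EnzymeSpec
    position: int | None  # None = uncut required
    tolerance: int = 5

    def holds(self, result: DigestResult) -> bool:
        if self.position is None:
            return not result.cut_positions
        return any(
            abs(c - self.position) <= self.tolerance
            for c in result.cut_positions
        )


@dataclass(frozen=True)
class LineageRule:
    label: str
    predicates: tuple[DigestPredicate, ...]


@dataclass
class LineageRuleSet:
    """Ordered decision list mapping digest patterns to lineage labels."""

    rules: tuple[LineageRule, ...]

    def enzymes(self) -> list[EnzymeSpec]:
        seen = {}
        for rule in self.rules:
            for pred in rule.predicates:
                seen.setdefault(pred.enzyme.name, pred.enzyme)
        return list(seen.values())


def default_ruleset(tolerance: int = 5) -> LineageRuleSet:
    """The four-lineage assay: SspI splits central / south / (SW+NW) and
    DraI then separates northwest from southwest.

    SspI uncut -> central; SspI cut near 598 -> south; SspI cut near 166
    with DraI cut near 227 -> northwest, DraI uncut -> southwest.
    """
    return LineageRuleSet(rules=(
        LineageRule("south", (DigestPredicate(SSPI, 598, tolerance),)),
        LineageRule("northwest", (
            DigestPredicate(SSPI, 166, tolerance),
            DigestPredicate(DRAI, 227, tolerance),
        )),
        LineageRule("southwest", (
            DigestPredicate(SSPI, 166, tolerance),
            DigestPredicate(DRAI, None, tolerance),
        )),
        LineageRule("central", (DigestPredicate(SSPI, None, tolerance),)),
    ))


def assign_lineage(sequence: str, ruleset: LineageRuleSet | None = None) -> str:
    """Classify one amplicon by its digest pattern; first matching rule wins."""
    ruleset = ruleset or default_ruleset()
    digests = {e.name: digest(sequence, e) for e in ruleset.enzymes()}
    for rule in ruleset.rules:
        if all(p.holds(digests[p.enzyme.name]) for p in rule.predicates):
            return rule.label
    return UNASSIGNED


def lineage_site_frequencies(dataset: TransectDataset) -> pd.DataFrame:
    """Per-site mtDNA lineage frequencies, modal lineage, and flags.

    Frequencies are over assigned individuals only; sites with none are
    flagged ``empty`` rather than failing.  A 50/50 modal split sets the
    ``tie`` flag.
    """
    labels = sorted(set(dataset.mtdna_lineage.values()))
    rows = []
    for site in dataset.site_ids:
        inds = [
            i for i in dataset.genotypes.individual_ids
            if dataset.genotypes.site_of[i] == site
        ]
        assigned = [
            dataset.mtdna_lineage[i] for i in inds
            if dataset.mtdna_lineage.get(i) not in (None, UNASSIGNED)
        ]
        row: dict = {"site": site, "n_assigned": len(assigned),
                     "empty": len(assigned) == 0, "tie": False, "mode": None}
        if assigned:
            counts = {lab: assigned.count(lab) for lab in labels}
            total = len(assigned)
            for lab in labels:
                row[lab] = counts.get(lab, 0) / total
            top = max(counts.values())
            modes = [lab for lab, c in counts.items() if c == top]
            row["mode"] = modes[0]
            row["tie"] = len(modes) > 1
        else:
            for lab in labels:
                row[lab] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("site")
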