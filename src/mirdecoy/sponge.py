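"""Design of miRNA decoy (sponge) sites and multi-site cassettes.

A *perfect* site is the exact reverse complement of the mature miRNA.  A
*bulged* site keeps the seed-pairing 3' region intact but replaces the
complement of the miRNA's central positions (9-12 by default) with a shorter
run of deliberately non-complementary nucleotides, so Argonaute binds without
cleaving and the decoy sequesters the miRNA for longer.  Cassettes string
several sites together with short spacers between restriction-site flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
# G.U wobbles also pair; a true mismatch must avoid both partners.
WOBBLE_PARTNER = {"G": "U", "U": "G"}

SEED_START, SEED_END = 2, 8  # miRNA seed, 1-based inclusive


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA sequence (5'->3' in, 5'->3' out)."""
    return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


@dataclass
class MatureMiRNA:
    """A mature miRNA, 5'->3', 19-25 nt; the seed is positions 2-8."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"{self.id}: illegal character {sorted(bad)[0]}")
        if not 19 <= len(seq) <= 25:
            raise ValueError(f"{self.id}: mature miRNA length must be 19-25, got {len(seq)}")
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def seed(self) -> str:
        return self.sequence[SEED_START - 1 : SEED_END]

    @property
    def seed_match(self) -> str:
        """The 7-mer a target carries to pair the seed (reverse complement of it)."""
        return reverse_complement(self.seed)


@dataclass
class SpongeSite:
    """One decoy site (RNA, 5'->3') with its design provenance."""

    mirna_id: str
    site_sequence: str
    design: str  # "perfect" | "bulged"
    mismatch_positions: list[int] = field(default_factory=list)

    def as_dna(self) -> str:
        return rna_to_dna(self.site_sequence)


@dataclass
class SpongeCassette:
    """An ordered run of decoy sites with spacers and restriction-site flanks."""

    sites: list[SpongeSite]
    spacers: list[str]
    flank_5: str
    flank_3: str

    def __post_init__(self) -> None:
        if len(self.spacers) != max(len(self.sites) - 1, 0):
            raise ValueError(
                f"need {len(self.sites) - 1} spacers for {len(self.sites)} sites, "
                f"got {len(self.spacers)}"
            )

    @property
    def full_sequence(self) -> str:
        parts = [self.flank_5]
        for k, site in enumerate(self.sites):
            parts.append(site.as_dna())
            if k < len(self.spacers):
                parts.append(self.spacers[k])
        parts.append(self.flank_3)
        return "".join(parts)


def perfect_site(mirna: MatureMiRNA) -> SpongeSite:
    """The fully complementary decoy site (cleavable by Ago2)."""
    return SpongeSite(mirna.id, reverse_complement(mirna.sequence), "perfect", [])


def bulged_site(
    mirna: MatureMiRNA,
    bulge_start: int = 9,
    replaced_len: int = 4,
    inserted_len: int = 3,
    seed_rng: int | np.random.Generator | None = 0,
) -> SpongeSite:
    """A central-bulge decoy site.

    The reverse complement of miRNA positions ``[bulge_start,
    bulge_start+replaced_len-1]`` is excised from the perfect site and
    replaced by ``inserted_len`` nucleotides, each drawn (seeded) to be
    non-complementary (Watson-Crick or wobble) to the miRNA base it faces.
    With the defaults a 23-nt miRNA yields a 22-nt site carrying exactly 3
    mismatched nucleotides opposite positions 9-12.
    """
    L = len(mirna)
    lo, hi = bulge_start, bulge_start + replaced_len - 1
    if lo <= SEED_END:
        raise ValueError("seed must remain paired: bulge window overlaps positions 1-8")
    if hi > L - 2:
        raise ValueError("bulge window overlaps the final 2 nt of the miRNA")
    rng = np.random.default_rng(seed_rng) if not isinstance(seed_rng, np.random.Generator) else seed_rng

    perfect = reverse_complement(mirna.sequence)
    # Site positions are antiparallel: miRNA position p sits at site index L - p.
    s0 = L - hi  # 0-based site index of the first replaced nucleotide
    inserted = []
    for t in range(inserted_len):
        facing = mirna.sequence[hi - 1 - t]  # miRNA base opposite inserted nt t
        banned = {RNA_COMPLEMENT[facing]}
        if facing in WOBBLE_PARTNER:
            banned.add(WOBBLE_PARTNER[facing])
        choices = sorted(set("ACGU") - banned)
        inserted.append(choices[rng.integers(len(choices))])
    site = perfect[:s0] + "".join(inserted) + perfect[s0 + replaced_len :]
    return SpongeSite(mirna.id, site, "bulged", list(range(lo, hi + 1)))


def build_cassette(
    sites: Sequence[SpongeSite],
    spacers: Sequence[str] = ("ATGC", "GTAC", "TGCA"),
    flank_5: str = "CGAT",
    flank_3: str = "T",
) -> SpongeCassette:
    """Assemble sites and spacers between restriction-site flanks."""
    if len(spacers) != len(sites) - 1:
        raise ValueError(
            f"need {len(sites) - 1} spacers for {len(sites)} sites, got {len(spacers)}"
        )
    return SpongeCassette(list(sites), [s.upper() for s in spacers], flank_5.upper(), flank_3.upper())


def count_sites(construct: str, site: SpongeSite | str) -> int:
    """Non-overlapping occurrences of the site (as DNA) in a construct, left to right."""
    motif = site.as_dna() if isinstance(site, SpongeSite) else rna_to_dna(site.upper())
    construct = construct.upper().replace("U", "T")
    count, pos = 0, 0
    while motif:
        hit = construct.find(motif, pos)
        if hit < 0:
            break
        count += 1
        pos = hit + len(motif)
    return count


@dataclass
class CassetteReport:
    """Validation summary for a cassette against the miRNAs it should trap."""

    missing_flanks: list[str]
    site_counts: dict[str, int]
    unintended_seed_hits: dict[str, list[int]]

    @property
    def ok(self) -> bool:
        return not self.missing_flanks and not any(self.unintended_seed_hits.values())


def validate_cassette(cassette: SpongeCassette, mirnas: Iterable[MatureMiRNA]) -> CassetteReport:
    """Report missing flanks, per-miRNA site counts and stray seed matches.

    A stray seed match is an occurrence of a miRNA's 7-mer seed complement in
    the full cassette outside any designed site span: it would create an
    unintended (seed-only) decoy.
    """
    full = cassette.full_sequence
    missing = []
    if not cassette.flank_5 or not full.startswith(cassette.flank_5):
        missing.append("flank_5")
    if not cassette.flank_3 or not full.endswith(cassette.flank_3):
        missing.append("flank_3")

    # Designed site spans within the assembled sequence.
    spans: list[tuple[int, int]] = []
    pos = len(cassette.flank_5)
    for k, site in enumerate(cassette.sites):
        spans.append((pos, pos + len(site.site_sequence)))
        pos += len(site.site_sequence)
        if k < len(cassette.spacers):
            pos += len(cassette.spacers[k])

    site_counts: dict[str, int] = {}
    stray: dict[str, list[int]] = {}
    for mirna in mirnas:
        designed = [s for s in cassette.sites if s.mirna_id == mirna.id]
        site_counts[mirna.id] = sum(count_sites(full, s) for s in {s.site_sequence: s for s in designed}.values())
        seed_dna = rna_to_dna(mirna.seed_match)
        hits = []
        start = 0
        while True:
            hit = full.find(seed_dna, start)
            if hit < 0:
                break
            inside = any(a <= hit and hit + len(seed_dna) <= b for a, b in spans)
            if not inside:
                hits.append(hit)
            start = hit + 1
        stray[mirna.id] = hits
    return CassetteReport(missing, site_counts, stray)
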