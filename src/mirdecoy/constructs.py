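"""Published sponge constructs and the mature miRNAs they sequester.

The two sponge oligonucleotides were chemically synthesized for the original
study and their sense-strand sequences are public; they serve here both as
reference inputs and as ground truth for the cassette parser/validator.

``MIR155_MATURE`` is the canonical miRBase mmu-miR-155-5p sequence and is
consistent with the miR155T oligo under the bulged-site design rule.
``MIR802_MATURE`` is reconstructed by inverting that design rule on the
miR802T oligo (a 21-nt site implies a 22-nt mature under a 4-replaced /
3-inserted central bulge); it is a reconstruction, not a literature copy.
"""

# Sense strands as synthesized (DNA): 4 decoy sites separated by 4-nt spacers,
# flanked by restriction half-sites (ClaI/XbaI and EcoRI/KpnI respectively).
MIR155T_OLIGO = (
    "CGATACCCCTATCACAGGAGCATTAAATGCACCCCTATCACAGGAGCATTAAGTACACCCC"
    "TATCACAGGAGCATTAATGCAACCCCTATCACAGGAGCATTAAT"
)
MIR802T_OLIGO = (
    "AATTCAAGGATGAATTGTGTTACTGAATGCAAGGATGAATTGTGTTACTGAGTACAAGGAT"
    "GAATTGTGTTACTGATGCAAAGGATGAATTGTGTTACTGAGGTAC"
)

# The repeated decoy site motifs (DNA sense strand).
MIR155T_SITE = "ACCCCTATCACAGGAGCATTAA"
MIR802T_SITE = "AAGGATGAATTGTGTTACTGA"

MIR155_MATURE = "UUAAUGCUAAUUGUGAUAGGGGU"  # mmu-miR-155-5p, 23 nt
MIR802_MATURE = "UCAGUAACAAAGAUUCAUCCUU"  # mmu-miR-802, 22 nt (reconstructed)

DEFAULT_SPACERS = ("ATGC", "GTAC", "TGCA")


def extract_site_motif(oligo: str, n_sites: int = 4) -> str:
    """Recover the repeated decoy-site motif from a cassette sense strand.

    Returns the longest substring that occurs at least ``n_sites`` times
    without overlap, scanning left to right.  For the published cassettes
    this is the 21/22-nt decoy site.
    """
    oligo = oligo.upper()
    best = ""
    for length in range(len(oligo) // n_sites, 3, -1):
        for start in range(0, len(oligo) - length + 1):
            motif = oligo[start : start + length]
            count, pos = 0, 0
            while True:
                hit = oligo.find(motif, pos)
                if hit < 0:
                    break
                count += 1
                pos = hit + length
            if count >= n_sites:
                return motif
    return best
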