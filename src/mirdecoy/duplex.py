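"""Intermolecular RNA:RNA hybridization minimum free energy.

The model class is the one the RNAhybrid family of tools uses: the two
strands form a single duplex of stacked base pairs interrupted by bulges and
interior loops; neither strand pairs with itself and pseudoknots are
impossible by construction.  Unpaired strand ends dangle free.  The energy of
a structure is

    duplex_initiation + sum(stacks) + sum(loop penalties) + terminal penalties

with nearest-neighbor stacking free energies (Turner-style, including G.U
wobble pairs), affine bulge/interior-loop penalties capped at ``max_loop``
unpaired nucleotides per strand, and an AU/GU closing penalty at the two
outermost pairs.  Parameters are loaded from a versioned bundled text file so
reported energies are tied to a parameter version.

``duplex_mfe`` is an exact dynamic program over all such structures;
``brute_force_mfe`` enumerates them explicitly on small inputs and is kept
independent as a test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sponge import MatureMiRNA, SpongeSite, bulged_site, perfect_site, reverse_complement

CAN_PAIR = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)
AU_LIKE = frozenset([("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")])

DEFAULT_PARAMS_FILE = "rna_nn_params_v1.tsv"


@dataclass
class EnergyParameters:
    """Nearest-neighbor hybridization parameters (kcal/mol at 37 C)."""

    stack: dict[tuple[str, str], float]
    duplex_initiation: float
    terminal_au_penalty: float
    bulge_init: float
    bulge_slope: float
    interior_init: float
    interior_slope: float
    interior_asym: float
    max_loop: int
    version: str = "unversioned"

    def can_pair(self, a: str, b: str) -> bool:
        return (a, b) in CAN_PAIR

    def stack_energy(self, top: str, bottom: str) -> float:
        """Energy of the stack with top doublet 5'->3' and bottom doublet 3'->5'."""
        return self.stack[(top, bottom)]

    def bulge_penalty(self, size: int) -> float:
        if size <= 0:
            raise ValueError("bulge size must be positive")
        if size > self.max_loop:
            return math.inf
        return self.bulge_init + self.bulge_slope * size

    def interior_penalty(self, size_a: int, size_b: int) -> float:
        if size_a <= 0 or size_b <= 0:
            raise ValueError("interior loop sides must be positive")
        if size_a > self.max_loop or size_b > self.max_loop:
            return math.inf
        return (
            self.interior_init
            + self.interior_slope * (size_a + size_b)
            + self.interior_asym * abs(size_a - size_b)
        )

    def terminal_penalty(self, a: str, b: str) -> float:
        return self.terminal_au_penalty if (a, b) in AU_LIKE else 0.0

    def loop_penalty(self, gap_a: int, gap_b: int) -> float:
        """Penalty for the loop between consecutive pairs, by unpaired counts."""
        if gap_a == 0 and gap_b == 0:
            raise ValueError("adjacent pairs form a stack, not a loop")
        if gap_a == 0 or gap_b == 0:
            return self.bulge_penalty(gap_a + gap_b)
        return self.interior_penalty(gap_a, gap_b)


def load_parameters(path: str | Path) -> EnergyParameters:
    stack: dict[tuple[str, str], float] = {}
    scalars: dict[str, float] = {}
    version = Path(path).stem
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "stack":
                _, top, bottom, e = fields
                stack[(top, bottom)] = float(e)
            elif fields[0] == "param":
                scalars[fields[1]] = float(fields[2])
    return EnergyParameters(
        stack=stack,
        duplex_initiation=scalars["duplex_initiation"],
        terminal_au_penalty=scalars["terminal_au_penalty"],
        bulge_init=scalars["bulge_init"],
        bulge_slope=scalars["bulge_slope"],
        interior_init=scalars["interior_init"],
        interior_slope=scalars["interior_slope"],
        interior_asym=scalars["interior_asym"],
        max_loop=int(scalars["max_loop"]),
        version=version,
    )


def load_default_parameters() -> EnergyParameters:
    ref = resources.files("mirdecoy").joinpath("data", DEFAULT_PARAMS_FILE)
    with resources.as_file(ref) as path:
        return load_parameters(path)


@dataclass
class DuplexResult:
    """Optimal hybridization: energy, pairing map and additive decomposition."""

    mfe: float
    pairing: list[tuple[int, int]]  # 1-based (miRNA position, site position)
    decomposition: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)


def _check_rna(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"{name}: non-RNA character {sorted(bad)[0]}")
    return seq


def _as_seq(x: MatureMiRNA | SpongeSite | str) -> str:
    if isinstance(x, MatureMiRNA):
        return x.sequence
    if isinstance(x, SpongeSite):
        return x.site_sequence
    return x


def energy_of_structure(
    pairing: Sequence[tuple[int, int]],
    a: str,
    b: str,
    params: EnergyParameters | None = None,
) -> float:
    """Score an explicit monotone pairing between strands ``a`` and ``b``.

    ``pairing`` holds 1-based (i, j) pairs; the strands are antiparallel, so
    successive pairs must increase in i and decrease in j.  Crossing pairs
    raise; loops beyond the size cap score +inf.
    """
    params = params or load_default_parameters()
    a, b = _check_rna(a, "a"), _check_rna(b, "b")
    total = params.duplex_initiation
    if not pairing:
        return total
    pairs = sorted(pairing)
    last_i, last_j = None, None
    for i, j in pairs:
        if not (1 <= i <= len(a) and 1 <= j <= len(b)):
            raise ValueError(f"pair ({i},{j}) out of range")
        if not params.can_pair(a[i - 1], b[j - 1]):
            raise ValueError(f"bases at ({i},{j}) cannot pair")
        if last_i is not None and j >= last_j:
            raise ValueError("crossing pairs: structure is not a monotone duplex")
        if last_i is not None:
            gap_a, gap_b = i - last_i - 1, last_j - j - 1
            if gap_a == 0 and gap_b == 0:
                total += params.stack_energy(a[last_i - 1] + a[i - 1], b[last_j - 1] + b[j - 1])
            else:
                total += params.loop_penalty(gap_a, gap_b)
        last_i, last_j = i, j
    first_i, first_j = pairs[0]
    total += params.terminal_penalty(a[first_i - 1], b[first_j - 1])
    total += params.terminal_penalty(a[last_i - 1], b[last_j - 1])
    return total


def duplex_mfe(
    mirna: MatureMiRNA | str,
    site: SpongeSite | str,
    params: EnergyParameters | None = None,
    allow_bulges: bool = True,
    allow_interior: bool = True,
) -> DuplexResult:
    """Global minimum-free-energy hybridization of two RNA strands.

    Exact DP over all duplex structures of the model class (stacks, bulges,
    interior loops; no intramolecular pairs).  Ties are broken toward more
    paired bases, then toward the lexicographically smallest pairing.
    """
    params = params or load_default_parameters()
    a = _check_rna(_as_seq(mirna), "mirna")
    b = _check_rna(_as_seq(site), "site")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both sequences must have length >= 2")
    n, m = len(a), len(b)
    W = params.max_loop

    INF = math.inf
    # E[i][j]: best energy of a duplex whose 5'(a)-outermost pair already paid
    # its terminal penalty and whose current innermost pair is (i, j), 0-based.
    E = np.full((n, m), INF)
    NP = np.zeros((n, m), dtype=int)  # pair count of the chosen chain
    PREV: dict[tuple[int, int], tuple[int, int] | None] = {}

    pairable = [[params.can_pair(a[i], b[j]) for j in range(m)] for i in range(n)]

    for i in range(n):
        for j in range(m - 1, -1, -1):
            if not pairable[i][j]:
                continue
            best = params.duplex_initiation + params.terminal_penalty(a[i], b[j])
            best_key = (round(best, 9), -1, -1, -1)
            best_prev: tuple[int, int] | None = None
            best_np = 1
            for k in range(max(0, i - W - 1), i):
                gap_a = i - k - 1
                for l in range(j + 1, min(m, j + W + 2)):
                    if E[k, l] == INF:
                        continue
                    gap_b = l - j - 1
                    if gap_a == 0 and gap_b == 0:
                        step = params.stack_energy(a[k] + a[i], b[l] + b[j])
                    elif gap_a == 0 or gap_b == 0:
                        if not allow_bulges:
                            continue
                        step = params.bulge_penalty(gap_a + gap_b)
                    else:
                        if not allow_interior:
                            continue
                        step = params.interior_penalty(gap_a, gap_b)
                    if step == INF:
                        continue
                    cand = E[k, l] + step
                    key = (round(cand, 9), -(NP[k, l] + 1), k, l)
                    if key < best_key:
                        best_key = key
                        best = cand
                        best_prev = (k, l)
                        best_np = NP[k, l] + 1
            E[i, j] = best
            NP[i, j] = best_np
            PREV[(i, j)] = best_prev

    # Close the duplex: add the terminal penalty of the innermost pair.
    best_end: tuple[int, int] | None = None
    best_key = (round(params.duplex_initiation, 9), 0, -1, -1)  # empty structure
    mfe = params.duplex_initiation
    for i in range(n):
        for j in range(m):
            if E[i, j] == INF:
                continue
            total = E[i, j] + params.terminal_penalty(a[i], b[j])
            key = (round(total, 9), -NP[i, j], i, j)
            if key < best_key:
                best_key = key
                best_end = (i, j)
                mfe = total

    pairing: list[tuple[int, int]] = []
    node = best_end
    while node is not None:
        pairing.append((node[0] + 1, node[1] + 1))
        node = PREV[node]
    pairing.sort()

    decomposition = _decompose(pairing, a, b, params)
    return DuplexResult(mfe=mfe, pairing=pairing, decomposition=decomposition)


def _decompose(
    pairing: list[tuple[int, int]], a: str, b: str, params: EnergyParameters
) -> list[tuple[str, float]]:
    terms: list[tuple[str, float]] = [("initiation", params.duplex_initiation)]
    if not pairing:
        return terms
    first_i, first_j = pairing[0]
    last_i, last_j = pairing[-1]
    for (pi, pj), (ci, cj) in zip(pairing, pairing[1:]):
        gap_a, gap_b = ci - pi - 1, pj - cj - 1
        if gap_a == 0 and gap_b == 0:
            top, bottom = a[pi - 1] + a[ci - 1], b[pj - 1] + b[cj - 1]
            terms.append((f"stack {top}/{bottom}", params.stack_energy(top, bottom)))
        elif gap_a == 0 or gap_b == 0:
            size = gap_a + gap_b
            terms.append((f"bulge {size}", params.bulge_penalty(size)))
        else:
            terms.append((f"interior {gap_a}x{gap_b}", params.interior_penalty(gap_a, gap_b)))
    for label, (i, j) in (("terminal_5p", (first_i, first_j)), ("terminal_3p", (last_i, last_j))):
        pen = params.terminal_penalty(a[i - 1], b[j - 1])
        if pen:
            terms.append((label, pen))
    return terms


def brute_force_mfe(
    a: str, b: str, params: EnergyParameters | None = None
) -> DuplexResult:
    """Exact MFE by explicit enumeration of all monotone pairings (test oracle).

    Independent of the DP: recursively extends a chain of pairs (increasing in
    a, decreasing in b), scoring each complete structure with
    :func:`energy_of_structure`.  Capped at len(a)*len(b) <= 64.
    """
    params = params or load_default_parameters()
    a, b = _check_rna(_as_seq(a), "a"), _check_rna(_as_seq(b), "b")
    if len(a) * len(b) > 64:
        raise ValueError("brute_force_mfe is capped at len(a)*len(b) <= 64")

    cells = [
        (i, j)
        for i in range(1, len(a) + 1)
        for j in range(1, len(b) + 1)
        if params.can_pair(a[i - 1], b[j - 1])
    ]

    best: tuple[float, int, list[tuple[int, int]]] = (
        round(params.duplex_initiation, 9),
        0,
        [],
    )

    def extend(chain: list[tuple[int, int]]) -> None:
        nonlocal best
        if chain:
            e = energy_of_structure(chain, a, b, params)
            if e != math.inf:
                key = (round(e, 9), -len(chain), chain)
                cur = (best[0], -best[1], best[2])
                if (key[0], key[1], key[2]) < cur:
                    best = (key[0], len(chain), list(chain))
        last = chain[-1] if chain else None
        for i, j in cells:
            if last is None or (i > last[0] and j < last[1]):
                chain.append((i, j))
                extend(chain)
                chain.pop()

    extend([])
    mfe_pairing = best[2]
    mfe = energy_of_structure(mfe_pairing, a, b, params) if mfe_pairing else params.duplex_initiation
    return DuplexResult(mfe=mfe, pairing=mfe_pairing, decomposition=_decompose(mfe_pairing, a, b, params))


def random_sites(
    n: int = 100, length: int = 22, seed: int | np.random.Generator | None = 0
) -> list[str]:
    """I.i.d. uniform random RNA sequences (the fully-random null category)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bases = np.array(list("ACGU"))
    return ["".join(bases[rng.integers(0, 4, size=length)]) for _ in range(n)]


def seed_fixed_random_sites(
    mirna: MatureMiRNA,
    n: int = 100,
    length: int = 22,
    seed: int | np.random.Generator | None = 0,
) -> list[str]:
    """Random sequences carrying the miRNA's 7-mer seed complement.

    The seed match is implanted where a perfect site would hold it: ending one
    nucleotide short of the site's 3' end, so miRNA positions 2-8 pair it.
    """
    if length < 9:
        raise ValueError("length must be >= 9 to hold a seed match")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seed_match = mirna.seed_match
    start = length - 8  # 0-based; occupies [length-8, length-1)
    out = []
    for s in random_sites(n, length, rng):
        out.append(s[:start] + seed_match + s[start + 7 :])
    return out


def category_report(
    mirna: MatureMiRNA,
    engineered_perfect: SpongeSite | None = None,
    engineered_bulged: SpongeSite | None = None,
    validated_sites: Iterable[str] = (),
    n_null: int = 100,
    null_length: int = 22,
    seed: int | np.random.Generator | None = 0,
    params: EnergyParameters | None = None,
) -> pd.DataFrame:
    """Per-category MFE summary mirroring the engineered/validated/null layout.

    Categories: engineered perfect site, engineered bulged site, validated
    endogenous sites (omitted when empty), fully random sequences, and random
    sequences with the miRNA seed match fixed.
    """
    params = params or load_default_parameters()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    engineered_perfect = engineered_perfect or perfect_site(mirna)
    engineered_bulged = engineered_bulged or bulged_site(mirna, seed_rng=rng)

    categories: list[tuple[str, list[str]]] = [
        ("engineered_perfect", [engineered_perfect.site_sequence]),
        ("engineered_bulged", [engineered_bulged.site_sequence]),
    ]
    validated = list(validated_sites)
    if validated:
        categories.append(("validated", validated))
    categories.append(("random", random_sites(n_null, null_length, rng)))
    categories.append(("random_fixed_seed", seed_fixed_random_sites(mirna, n_null, null_length, rng)))

    rows = []
    for name, sites in categories:
        mfes = np.array([duplex_mfe(mirna, s, params).mfe for s in sites])
        rows.append(
            {
                "mirna": mirna.id,
                "category": name,
                "n": len(mfes),
                "mean_mfe": float(mfes.mean()),
                "sd_mfe": float(mfes.std(ddof=1)) if len(mfes) > 1 else 0.0,
                "min_mfe": float(mfes.min()),
                "max_mfe": float(mfes.max()),
            }
        )
    return pd.DataFrame(rows)
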