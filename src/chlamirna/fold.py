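"""RNA secondary structure for hairpin detection.

The built-in folder is a maximum-base-pairing dynamic program (Watson-Crick
plus G:U wobble pairs, minimum hairpin loop of 3 unpaired nucleotides) with
a deterministic traceback that prefers stacked pairs.  It deliberately does
no thermodynamics: the downstream question is only whether a read cluster
folds into a single stem-loop with enough pairing to host a miRNA/miRNA*
duplex, for which pair counting is sufficient and exactly reproducible.
An external folding backend (an ``RNAfold``-compatible executable emitting
dot-bracket strings) can be substituted per call.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass

from .seqio import to_rna

_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: Watson-Crick complements, for "paired to a complementary base" checks.
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}

MIN_LOOP = 3


class FoldBackendError(RuntimeError):
    """The external folding backend could not be run."""


class MatureInLoopError(ValueError):
    """A mature interval overlaps the terminal loop of the hairpin."""


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass
class FoldResult:
    """A folded sequence: dot-bracket structure plus a pair table.

    ``pair_table[i]`` is the partner position of ``i`` or ``None``.
    """

    seq: str
    structure: str
    backend: str
    pair_table: list[int | None]

    def pairs(self) -> list[tuple[int, int]]:
        return [
            (i, j)
            for i, j in enumerate(self.pair_table)
            if j is not None and i < j
        ]

    def validate(self) -> None:
        if len(self.structure) != len(self.seq):
            raise ValueError("structure/sequence length mismatch")
        for i, j in self.pairs():
            if self.pair_table[j] != i:
                raise ValueError("pair table not symmetric")
            if j - i <= MIN_LOOP:
                raise ValueError(f"hairpin loop below {MIN_LOOP} at ({i},{j})")


@dataclass
class HairpinCandidate:
    """A single stem-loop: stem/loop intervals are offsets in the folded seq."""

    cluster_id: str | None
    strand: str
    fold: FoldResult
    stem5_interval: tuple[int, int]
    loop_interval: tuple[int, int]
    stem3_interval: tuple[int, int]
    n_stem_pairs: int


def pair_table_from_dotbracket(structure: str) -> list[int | None]:
    table: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return table


def fold_sequence(
    seq: str,
    backend: str = "builtin",
    min_loop: int = MIN_LOOP,
    rnafold_exe: str = "RNAfold",
) -> FoldResult:
    """Fold ``seq`` (RNA or DNA alphabet; converted to RNA) into a structure."""
    rna = to_rna(seq)
    if len(rna) < MIN_LOOP + 2:
        raise ValueError(f"sequence too short to fold ({len(rna)} nt)")
    if backend == "builtin":
        structure = _fold_builtin(rna, min_loop)
    elif backend == "external":
        structure = _fold_external(rna, rnafold_exe)
    else:
        raise ValueError(f"unknown folding backend {backend!r}")
    result = FoldResult(
        seq=rna,
        structure=structure,
        backend=backend,
        pair_table=pair_table_from_dotbracket(structure),
    )
    result.validate()
    return result


def _fold_builtin(rna: str, min_loop: int) -> str:
    n = len(rna)
    pairable = [
        [can_pair(rna[i], rna[j]) for j in range(n)] for i in range(n)
    ]
    if not any(
        pairable[i][j] for i in range(n) for j in range(i + min_loop + 1, n)
    ):
        return "." * n  # e.g. purely A/C sequence: nothing can pair
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            row_i = dp[i]
            best = dp[i + 1][j]
            v = row_i[j - 1]
            if v > best:
                best = v
            if pairable[i][j]:
                v = dp[i + 1][j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = row_i[k] + dp[k + 1][j]
                if v > best:
                    best = v
            row_i[j] = best

    # Traceback: prefer pairing (i, j) when co-optimal, which grows stacks
    # from the outside in; then left-unpaired, right-unpaired, bifurcation.
    # Deterministic left-to-right.
    table: list[int | None] = [None] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop or dp[i][j] == 0:
            continue
        target = dp[i][j]
        if pairable[i][j] and target == dp[i + 1][j - 1] + 1:
            table[i], table[j] = j, i
            stack.append((i + 1, j - 1))
            continue
        if target == dp[i + 1][j]:
            stack.append((i + 1, j))
            continue
        if target == dp[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j):
            if dp[i][k] + dp[k + 1][j] == target:
                stack.append((k + 1, j))
                stack.append((i, k))
                break
    return "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(table)
    )


def fold_hairpin(
    seq: str,
    min_loop: int = MIN_LOOP,
    gap_penalty: float = 0.5,
    max_step_gap: int = 6,
) -> FoldResult:
    """Best single-stem (inverted-repeat) fold of a sequence.

    Unconstrained maximum base pairing of a cluster window is generically
    dense and multibranched, which says nothing about precursor geometry.
    This fold instead restricts structures to a single nested chain of
    pairs (one helix system, one terminal loop) and maximizes
    ``pairs - gap_penalty * unpaired-bases-between-consecutive-pairs``,
    with at most ``max_step_gap`` skipped bases per arm between
    consecutive pairs.  A genuine precursor scores its near-contiguous
    stem; windows without an inverted repeat are left unpaired.  The
    result feeds :func:`detect_hairpin` / :func:`star_mismatch_count`.
    """
    rna = to_rna(seq)
    n = len(rna)
    if n < MIN_LOOP + 2:
        raise ValueError(f"sequence too short to fold ({n} nt)")
    # score[(i, j)] = best score of a chain whose outermost pair is (i, j)
    score: dict[tuple[int, int], float] = {}
    inner: dict[tuple[int, int], tuple[int, int] | None] = {}
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            if not can_pair(rna[i], rna[j]):
                continue
            best_val = 0.0
            best_inner: tuple[int, int] | None = None
            for di in range(1, max_step_gap + 2):
                for dj in range(1, max_step_gap + 2):
                    key = (i + di, j - dj)
                    if key not in score:
                        continue
                    value = score[key] - gap_penalty * (di - 1 + dj - 1)
                    if value > best_val + 1e-9:
                        best_val = value
                        best_inner = key
            score[(i, j)] = 1.0 + best_val
            inner[(i, j)] = best_inner

    table: list[int | None] = [None] * n
    if score:
        outer = max(score, key=lambda k: (score[k], k[1] - k[0], -k[0]))
        node: tuple[int, int] | None = outer
        while node is not None:
            table[node[0]], table[node[1]] = node[1], node[0]
            node = inner[node]
    structure = "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(table)
    )
    result = FoldResult(
        seq=rna,
        structure=structure,
        backend="builtin-hairpin",
        pair_table=table,
    )
    result.validate()
    return result


def _fold_external(rna: str, exe: str) -> str:
    try:
        proc = subprocess.run(
            [exe, "--noPS"],
            input=f">query\n{rna}\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except FileNotFoundError as exc:
        raise FoldBackendError(
            f"external folding backend {exe!r} not found on PATH; "
            "use backend='builtin' instead"
        ) from exc
    except subprocess.CalledProcessError as exc:
        raise FoldBackendError(f"{exe} failed: {exc.stderr}") from exc
    for line in proc.stdout.splitlines():
        token = line.split()[0] if line.split() else ""
        if token and set(token) <= {"(", ")", "."}:
            return token
    raise FoldBackendError(f"could not parse dot-bracket from {exe} output")


def detect_hairpin(
    fold: FoldResult,
    min_stem_pairs: int = 15,
    cluster_id: str | None = None,
    strand: str = "+",
) -> HairpinCandidate | None:
    """Return a hairpin iff the fold is a single nested stem with one loop.

    Every pair must be nested inside the previous one (no two helices side
    by side, hence no multibranch junction and exactly one terminal loop),
    and the stem must contain at least ``min_stem_pairs`` base pairs.
    """
    pairs = fold.pairs()
    if len(pairs) < max(1, min_stem_pairs):
        return None
    pairs.sort()
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j2 < j1):
            return None  # side-by-side helices: a second terminal loop
    outer_i, outer_j = pairs[0]
    inner_i, inner_j = pairs[-1]
    return HairpinCandidate(
        cluster_id=cluster_id,
        strand=strand,
        fold=fold,
        stem5_interval=(outer_i, inner_i + 1),
        loop_interval=(inner_i + 1, inner_j),
        stem3_interval=(inner_j, outer_j + 1),
        n_stem_pairs=len(pairs),
    )


def mature_arm(
    hairpin: HairpinCandidate, mature_interval: tuple[int, int]
) -> str | None:
    """Which arm holds a mature interval: '5p', '3p', or None.

    The interval must overlap exactly one stem.  Ends dangling outside
    the stem - past its outer end, or a base or two into the terminal
    loop - are tolerated (those positions are simply unpaired); an
    interval spanning the loop from stem to stem, or lying entirely
    within the loop, belongs to no arm.
    """
    start, end = mature_interval
    in5 = start < hairpin.stem5_interval[1] and hairpin.stem5_interval[0] < end
    in3 = start < hairpin.stem3_interval[1] and hairpin.stem3_interval[0] < end
    if in5 and not in3:
        return "5p"
    if in3 and not in5:
        return "3p"
    return None


def star_mismatch_count(
    hairpin: HairpinCandidate, mature_interval: tuple[int, int]
) -> int:
    """Count mature positions not matched by the complementary arm.

    A mature position counts as a mismatch when it is unpaired in the fold
    (including ends dangling outside the stem) or paired to a
    non-complementary base; a G:U wobble pair counts as a match.  The
    interval must sit on one arm: overlapping the terminal loop raises
    :class:`MatureInLoopError`, touching neither stem is an error.
    """
    start, end = mature_interval
    if mature_arm(hairpin, mature_interval) is None:
        loop_s, loop_e = hairpin.loop_interval
        if start < loop_e and loop_s < end:
            raise MatureInLoopError(
                f"mature interval [{start},{end}) spans or sits in the "
                f"terminal loop [{loop_s},{loop_e})"
            )
        raise ValueError(
            f"mature interval [{start},{end}) does not lie on either stem"
        )
    seq = hairpin.fold.seq
    table = hairpin.fold.pair_table
    mismatches = 0
    for pos in range(start, end):
        partner = table[pos] if 0 <= pos < len(table) else None
        if partner is None:
            mismatches += 1
        elif not can_pair(seq[pos], seq[partner]):  # defensive; folds only emit pairs
            mismatches += 1
    return mismatches
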