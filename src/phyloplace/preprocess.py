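"""From raw nucleotide fragments to trimmed, reference-aligned peptides.

The chain is: six-frame translation (standard genetic code; ambiguous
codons become 'X', internal stops stay as '*'), frame selection by
profile score, glocal affine-gap alignment of the chosen peptide
against per-column reference residue frequencies, rule-based removal of
poorly aligned columns (the Gblocks parameter scheme), and a minimum
post-trim length of 50 aligned residues.  The reference column space is
fixed throughout: trimming masks query residues instead of deleting
reference columns, so placement always sees the same coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .alphabet import AA_INDEX, N_STATES
from .msa import MSA

FRAMES = (1, 2, 3, -1, -2, -3)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_MAP[_stop] = "*"

GAP_OPEN = 11.0
GAP_EXTEND = 1.0


class PreprocessError(ValueError):
    pass


# ----------------------------------------------------------------------
# translation


def translate_frame(nt: str, frame: int) -> str:
    """Translate one frame (+1..+3 forward, -1..-3 on the reverse strand)."""
    if frame not in FRAMES:
        raise PreprocessError(f"frame must be one of {FRAMES}, got {frame}")
    seq = nt.upper().replace("U", "T")
    if frame < 0:
        seq = str(Seq(seq).reverse_complement())
    seq = seq[abs(frame) - 1 :]
    seq = seq[: len(seq) - len(seq) % 3]
    out = []
    for i in range(0, len(seq), 3):
        out.append(_CODON_MAP.get(seq[i : i + 3], "X"))
    return "".join(out)


def translate_six_frames(nt: str) -> dict[int, str]:
    """All six translations; trailing 1-2 nt are dropped per frame."""
    if not nt:
        raise PreprocessError("empty nucleotide sequence")
    return {f: translate_frame(nt, f) for f in FRAMES}


# ----------------------------------------------------------------------
# profile construction and alignment


def build_profile(msa: MSA, background: np.ndarray | None = None, pseudocount: float = 0.1):
    """Per-column residue frequencies with pseudocounts, plus background.

    Returns (profile (n_cols, 20), background (20,)); columns sum to 1.
    Background defaults to uniform; pass the substitution model's
    equilibrium frequencies when available.
    """
    counts = np.full((msa.n_cols, N_STATES), pseudocount)
    for seq in msa.rows.values():
        for j, ch in enumerate(seq):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[j, idx] += 1.0
    profile = counts / counts.sum(axis=1, keepdims=True)
    if background is None:
        background = np.full(N_STATES, 1.0 / N_STATES)
    return profile, np.asarray(background, dtype=float)


def _emission_scores(peptide: str, profile: np.ndarray, background: np.ndarray) -> np.ndarray:
    """(len(peptide), n_cols) log-odds emissions; missing residues score 0."""
    logodds = np.log(profile / background[None, :])  # (n_cols, 20)
    n, m = len(peptide), profile.shape[0]
    E = np.zeros((n, m))
    for i, ch in enumerate(peptide.upper()):
        idx = AA_INDEX.get(ch)
        if idx is not None:
            E[i] = logodds[:, idx]
    return E


def _align_dp(E: np.ndarray, want_path: bool):
    """Glocal affine DP: both query and reference flanks are free.

    Match state M, query-insertion Ix (residue skipped, discarded from
    the output) and reference-deletion Iy (column left as gap), with
    affine costs open=11, extend=1.  Returns (score, path) where path
    is a list of (peptide index, column index) matches.
    """
    n, m = E.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        # match: free restart (both flanks free) or continue any state
        prev = np.maximum.reduce([M[i - 1, :-1], Ix[i - 1, :-1], Iy[i - 1, :-1]])
        M[i, 1:] = E[i - 1] + np.maximum(prev, 0.0)
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - GAP_OPEN, Ix[i - 1, 1:] - GAP_EXTEND)
        # within-row scan via running max of M[i, k] + extend*k
        k = np.arange(m + 1, dtype=float)
        run = np.maximum.accumulate(M[i] + GAP_EXTEND * k)
        Iy[i, 1:] = run[:-1] - GAP_OPEN - GAP_EXTEND * (k[1:] - 1.0)
    score = float(M[1:, 1:].max()) if n and m else 0.0
    score = max(score, 0.0)
    if not want_path:
        return score, []
    if score <= 0.0:
        return score, []
    i, j = np.unravel_index(np.argmax(M[1:, 1:]), (n, m))
    i, j = int(i) + 1, int(j) + 1
    path = []
    state = "M"
    tol = 1e-6
    while i > 0 and j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            prev_candidates = (
                ("M", M[i - 1, j - 1]),
                ("Ix", Ix[i - 1, j - 1]),
                ("Iy", Iy[i - 1, j - 1]),
            )
            target = M[i, j] - E[i - 1, j - 1]
            if target <= tol:  # free restart
                nxt = None
                for s, val in prev_candidates:
                    if abs(val - target) <= tol:
                        nxt = s
                        break
                if nxt is None:
                    break
                state = nxt
            else:
                state = min(prev_candidates, key=lambda sv: abs(sv[1] - target))[0]
            i, j = i - 1, j - 1
        elif state == "Ix":
            if abs(Ix[i, j] - (M[i - 1, j] - GAP_OPEN)) <= tol:
                state = "M"
            i -= 1
        else:  # Iy
            if abs(Iy[i, j] - (M[i, j - 1] - GAP_OPEN)) <= tol:
                state = "M"
            j -= 1
    path.reverse()
    return score, path


def align_to_profile(peptide: str, profile: np.ndarray, background: np.ndarray) -> float:
    """Best glocal log-odds score of the peptide against the profile."""
    if not peptide:
        return 0.0
    E = _emission_scores(peptide, profile, background)
    score, _ = _align_dp(E, want_path=False)
    return score


def align_to_reference(peptide: str, profile: np.ndarray, background: np.ndarray) -> str:
    """Aligned row in reference coordinates: one symbol per column.

    Unmatched columns are '-'; peptide residues aligned as insertions
    relative to the reference are discarded (the column space is fixed).
    """
    if not peptide:
        raise PreprocessError("empty peptide")
    E = _emission_scores(peptide, profile, background)
    _, path = _align_dp(E, want_path=True)
    row = ["-"] * profile.shape[0]
    pep = peptide.upper()
    for i, j in path:
        row[j] = pep[i]
    return "".join(row)


def shuffle_null_scores(
    peptide: str,
    profile: np.ndarray,
    background: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Profile scores of residue-shuffled copies of the peptide."""
    rng = np.random.default_rng(seed)
    chars = np.array(list(peptide))
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        out[i] = align_to_profile("".join(rng.permutation(chars)), profile, background)
    return out


def detection_threshold(
    peptide: str,
    profile: np.ndarray,
    background: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
    quantile: float = 0.99,
) -> float:
    """Score a real hit must exceed: the 99th percentile of shuffles."""
    null = shuffle_null_scores(peptide, profile, background, n_shuffles, seed)
    return float(np.quantile(null, quantile))


def select_frame(
    peptides: dict[int, str], profile: np.ndarray, background: np.ndarray
) -> tuple[int, float]:
    """Best-scoring frame; ties break in the order +1,+2,+3,-1,-2,-3."""
    best_frame, best_score = FRAMES[0], -np.inf
    for f in FRAMES:
        s = align_to_profile(peptides.get(f, ""), profile, background)
        if s > best_score:
            best_frame, best_score = f, s
    return best_frame, best_score


# ----------------------------------------------------------------------
# Gblocks-style trimming


@dataclass
class TrimParams:
    """Gblocks parameter scheme (only b2..b5 are tunable here).

    b1: identical-residue count making a column "conserved" (majority);
    b2: identical-residue count for a "highly conserved" flank position;
    b3: longest tolerated stretch of contiguous nonconserved columns;
    b4: minimum block length; b5: gap allowance — 'h' removes columns
    with more than half gaps.
    """

    n_rows: int
    b3: int = 15
    b4: int = 3
    b5: str = "h"
    b2: int | None = None
    b1: int | None = None

    def __post_init__(self):
        if self.b4 < 1:
            raise PreprocessError("minimum block length b4 must be >= 1")
        if self.b3 < 0:
            raise PreprocessError("b3 must be >= 0")
        if self.b1 is None:
            self.b1 = self.n_rows // 2 + 1
        if self.b2 is None:
            self.b2 = max(math.ceil(0.55 * self.n_rows), self.b1)
        if self.b2 < self.b1:
            raise PreprocessError("flank threshold b2 cannot be below the conservation threshold b1")


def _column_status(msa: MSA, params: TrimParams) -> tuple[np.ndarray, np.ndarray]:
    """Per column: status 0/1/2 (non-/conserved/highly) and gap-rule flag."""
    status = np.zeros(msa.n_cols, dtype=np.int8)
    gappy = np.zeros(msa.n_cols, dtype=bool)
    seqs = list(msa.rows.values())
    n = len(seqs)
    for j in range(msa.n_cols):
        col = [s[j] for s in seqs]
        gaps = sum(1 for c in col if c == "-")
        if (params.b5 == "h" and gaps * 2 > n) or (params.b5 == "n" and gaps > 0):
            gappy[j] = True
            status[j] = 0
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c in AA_INDEX:
                counts[c] = counts.get(c, 0) + 1
        top = max(counts.values(), default=0)
        if top >= params.b2:
            status[j] = 2
        elif top >= params.b1:
            status[j] = 1
    return status, gappy


def trim_columns(msa: MSA, params: TrimParams | None = None) -> np.ndarray:
    """Boolean mask of columns surviving the block-trimming rules.

    Steps: classify columns (the gap rule forces nonconserved); reject
    stretches of more than b3 contiguous nonconserved columns; trim
    each remaining block's flanks back to highly conserved positions;
    drop blocks shorter than b4; gap-rule columns never survive.
    """
    if params is None:
        params = TrimParams(n_rows=msa.n_rows)
    status, gappy = _column_status(msa, params)
    n = msa.n_cols
    keep = np.ones(n, dtype=bool)
    # reject long nonconserved stretches
    j = 0
    while j < n:
        if status[j] == 0:
            k = j
            while k < n and status[k] == 0:
                k += 1
            if k - j > params.b3:
                keep[j:k] = False
            j = k
        else:
            j += 1
    # blocks = contiguous kept runs; trim flanks to highly conserved
    mask = np.zeros(n, dtype=bool)
    j = 0
    while j < n:
        if not keep[j]:
            j += 1
            continue
        k = j
        while k < n and keep[k]:
            k += 1
        block = np.arange(j, k)
        hc = block[status[block] == 2]
        if hc.size:
            block = np.arange(hc[0], hc[-1] + 1)
            if block.size >= params.b4:
                mask[block] = True
        j = k
    mask[gappy] = False
    return mask


def apply_trim_to_query(query_row: str, mask: np.ndarray) -> str:
    """Blank query residues at removed columns (reference coordinates kept)."""
    return "".join(c if m else "-" for c, m in zip(query_row, mask))


def length_filter(aligned_row: str, min_len: int = 50) -> bool:
    """Keep a post-trim row iff it has at least ``min_len`` residues (>= is keep)."""
    return sum(1 for c in aligned_row if c != "-") >= min_len


# ----------------------------------------------------------------------
# multi-marker concatenation


def concatenate_markers(
    query_rows: dict[str, str | None],
    references: dict[str, MSA],
    marker_order: list[str] | None = None,
) -> tuple[str, MSA]:
    """Column-wise concatenation over a fixed marker order.

    All marker reference alignments must share one taxon set; a marker
    missing from the fragment contributes all-gap query columns.
    """
    order = marker_order if marker_order is not None else list(references)
    taxa = None
    for m in order:
        s = set(references[m].rows)
        if taxa is None:
            taxa = s
            first_labels = references[m].labels
        elif s != taxa:
            raise PreprocessError(f"marker {m!r} has a mismatched taxon set")
    parts_q: list[str] = []
    cat_rows = {l: "" for l in first_labels}
    for m in order:
        ref = references[m]
        row = query_rows.get(m)
        parts_q.append(row if row is not None else "-" * ref.n_cols)
        for l in first_labels:
            cat_rows[l] += ref[l]
    return "".join(parts_q), MSA(cat_rows)
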