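"""Tandem-repeat unit discovery and edit-tolerant decomposition.

Control-region sequences (and the CR lncRNAs transcribed from them) are
built from a small set of short repeat units with heterogeneous copy number
and order, plus polymorphic sites (including length-variant alleles).  Unit
candidates are found by self-match periodicity (a period-``p`` tandem run
makes ``seq[k] == seq[k-p]`` over the run); a consensus per unit is taken by
column majority over the copies after phase optimisation.  Decomposition is
a dynamic-programming tiling of the sequence by unit copies (each within a
per-copy edit budget), with one optional terminal partial unit and untiled
flanks; stored copy sequences are the literal input substrings, so the
decomposition always reconstructs its input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

DEFAULT_MIN_UNIT = 10
DEFAULT_MAX_UNIT = 50
DEFAULT_MIN_COPIES = 2
DEFAULT_MAX_EDITS = 3

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass(frozen=True)
class RepeatUnitType:
    id: str
    consensus: str

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class RepeatBlock:
    unit_id: str
    copy_seq: str  # literal input substring
    edits: int


@dataclass
class RepeatDecomposition:
    sequence: str
    blocks: list[RepeatBlock] = field(default_factory=list)
    partial_tail: tuple[str, int] | None = None  # (unit_id, length)
    partial_seq: str = ""
    left_flank: str = ""
    right_flank: str = ""
    polymorphic_sites: list[tuple[str, int, tuple[str, ...]]] = field(
        default_factory=list
    )
    low_coverage: bool = False

    def reconstruct(self) -> str:
        return (
            self.left_flank
            + "".join(b.copy_seq for b in self.blocks)
            + self.partial_seq
            + self.right_flank
        )

    def copy_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.blocks:
            out[b.unit_id] = out.get(b.unit_id, 0) + 1
        return out

    def order_string(self) -> str:
        """Compact unit-order string, run-length encoded (e.g. "Ix17,II,III")."""
        runs: list[list] = []
        for b in self.blocks:
            if runs and runs[-1][0] == b.unit_id:
                runs[-1][1] += 1
            else:
                runs.append([b.unit_id, 1])
        parts = [f"{u}x{n}" if n > 1 else u for u, n in runs]
        if self.partial_tail:
            parts.append(f"{self.partial_tail[0]}(partial {self.partial_tail[1]})")
        return ",".join(parts)


def _edit_distance(a: str, b: str, k: int = -1) -> int:
    return edlib.align(a, b, mode="NW", k=k)["editDistance"]


def find_repeat_units(seq: str, min_unit: int = DEFAULT_MIN_UNIT,
                      max_unit: int = DEFAULT_MAX_UNIT,
                      min_copies: int = DEFAULT_MIN_COPIES,
                      max_edits: int = DEFAULT_MAX_EDITS) -> list[RepeatUnitType]:
    """Discover tandem repeat unit types in *seq*.

    Candidate periods come from long self-match runs at lag ``p``; each
    candidate region is phase-optimised (the frame maximising exact copy
    agreement with the column-majority consensus), and units must achieve at
    least *min_copies* tandem copies within the per-copy edit budget.
    Results are ordered by total covered length, labelled I, II, III, ...;
    candidates whose period is a multiple of an accepted unit's period over
    the same region are folded away.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_unit:
        return []
    candidates = []  # (coverage, period, region_start, region_end)
    for p in range(min_unit, min(max_unit, n // 2) + 1):
        match = [seq[k] == seq[k - p] for k in range(p, n)]
        # maximal runs tolerating isolated mismatch stretches <= max_edits
        k = 0
        while k < len(match):
            if not match[k]:
                k += 1
                continue
            j = k
            run_end = k
            while j < len(match):
                if match[j]:
                    run_end = j
                    j += 1
                    continue
                # tolerate a short mismatch stretch inside the run
                gap = 0
                while j < len(match) and not match[j] and gap <= max_edits:
                    gap += 1
                    j += 1
                if gap > max_edits or j >= len(match) or not match[j]:
                    break
            run_len = run_end - k + 1
            density = sum(match[k: run_end + 1]) / run_len
            if run_len >= (min_copies - 1) * p and density >= 0.8:
                # region includes the seeding copy, one period before the run
                candidates.append((run_len + p, p, k, run_end + p + 1))
            k = j + 1
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    accepted: list[tuple[RepeatUnitType, int, int, int]] = []  # unit, p, s, e
    units: list[RepeatUnitType] = []
    for coverage, p, s, e in candidates:
        folded = False
        for _, ap, as_, ae in accepted:
            overlap = max(0, min(e, ae) - max(s, as_))
            if overlap > 0.5 * (e - s) and p % ap == 0:
                folded = True
                break
        if folded:
            continue
        unit = _phase_optimised_consensus(seq, p, s, e, min_copies, max_edits)
        if unit is None:
            continue
        unit = _fundamental_period(unit)
        if len(unit) < min_unit:
            continue
        # distinct unit types must differ by more than the edit budget
        if any(
            u.length == len(unit) and _edit_distance(u.consensus, unit) <= max_edits
            for u in units
        ):
            continue
        units.append(RepeatUnitType(_ROMAN[len(units)], unit))
        accepted.append((units[-1], len(unit), s, e))
    return _rephase_units(seq, units, accepted)


def _exact_run(seq: str, cons: str, start: int) -> int:
    """Number of consecutive exact copies of *cons* at *start*."""
    p, n, i = len(cons), len(seq), start
    count = 0
    while i + p <= n and seq[i: i + p] == cons:
        count += 1
        i += p
    return count


def _rephase_units(seq, units, accepted):
    """Joint re-phasing: a block followed by a terminal partial copy admits
    several equally-scoring frames; the frame consistent with the *end* of
    the preceding block's exact tiling is the canonical one."""
    accepted = sorted(accepted, key=lambda t: t[2])
    out = {u.id: u.consensus for u in units}
    cur = None
    for unit, p, s, e in accepted:
        cons = out[unit.id]
        placed = False
        if cur is not None:
            best = None
            for r in range(p):
                rot = cons[r:] + cons[:r]
                cnt = _exact_run(seq, rot, cur)
                if cnt >= 2 and (best is None or cnt > best[0]):
                    best = (cnt, rot)
            if best is not None:
                out[unit.id] = best[1]
                cur += best[0] * p
                placed = True
        if not placed:
            # anchor at this unit's own region
            anchor = None
            for start in range(max(0, s - p), s + p + 1):
                cnt = _exact_run(seq, cons, start)
                if cnt >= 2 and (anchor is None or cnt > anchor[0]):
                    anchor = (cnt, start)
            if anchor is not None:
                cur = anchor[1] + anchor[0] * p
            else:
                cur = e
        if cur is not None:
            # step past a terminal exact partial copy of this unit
            cons2 = out[unit.id]
            k = 0
            while (cur + k < len(seq) and k < p - 1
                   and seq[cur + k] == cons2[k]):
                k += 1
            if k >= (p + 1) // 2 and cur + k >= len(seq):
                cur += k
    return [RepeatUnitType(u.id, out[u.id]) for u in units]


def _fundamental_period(cons: str) -> str:
    """Reduce a consensus that is itself a perfect tandem (e.g. a doubled
    period picked up at lag 2p) to its fundamental unit."""
    p = len(cons)
    for d in range(1, p // 2 + 1):
        if p % d == 0 and all(cons[i] == cons[i - d] for i in range(d, p)):
            return cons[:d]
    return cons


def _phase_optimised_consensus(seq, p, s, e, min_copies, max_edits):
    """Column-majority consensus of the period-*p* copies in region [s, e),
    choosing the phase whose consensus the most copies match exactly."""
    best = None  # (score, -phase, consensus)
    lo = max(0, s - p + 1)
    for start in range(lo, min(s + p, e - p * min_copies) + 1):
        m = (e - start) // p
        if m < min_copies:
            continue
        copies = [seq[start + i * p: start + (i + 1) * p] for i in range(m)]
        cons = "".join(
            max(set(col), key=lambda c: (col.count(c), c))
            for col in zip(*copies)
        )
        score = sum(c == cons for c in copies)
        # ties (a terminal partial copy makes a rotated frame score equally
        # well) break toward the frame whose first copy is consensus-exact,
        # then toward the run seed
        cand = (score, copies[0] == cons, -abs(start - s), cons)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    score, _, _, cons = best
    m = max(1, (e - s) // p)
    good = sum(
        _edit_distance(seq[i: i + p], cons, max_edits) >= 0
        for i in range(s, e - p + 1, p)
    )
    ok = score >= min_copies or (good >= min_copies and good >= 0.6 * m)
    return cons if ok else None


def decompose(seq: str, units: list[RepeatUnitType],
              max_edits: int = DEFAULT_MAX_EDITS) -> RepeatDecomposition:
    """Tile *seq* with unit copies by dynamic programming.

    The tiling is one contiguous chain of full-unit copies (each within
    *max_edits* substitutions/indels of its consensus, so length-variant
    alleles are absorbed), preceded/followed by untiled flanks, with one
    optional terminal partial unit (a consensus prefix of >=50% unit length)
    between the last block and the right flank.  Among maximal-coverage
    tilings the one with fewer edits, then fewer blocks, then
    lexicographically earliest unit ids wins.
    """
    if not units:
        raise ValueError("no repeat units supplied")
    seq = seq.upper()
    n = len(seq)
    units = sorted(units, key=lambda u: u.id)
    # chain[i]: best (coverage, -edits, -blocks) for a contiguous tiling
    # ending exactly at i, with backpointer (j, unit_index, edits)
    chain: list[tuple | None] = [None] * (n + 1)
    back: list[tuple | None] = [None] * (n + 1)
    for i in range(1, n + 1):
        for ui, u in enumerate(units):
            for L in range(max(1, u.length - max_edits), u.length + max_edits + 1):
                j = i - L
                if j < 0:
                    continue
                d = _edit_distance(seq[j:i], u.consensus, max_edits)
                if d < 0:
                    continue
                if chain[j] is None:
                    cand = (L, -d, -1)
                else:
                    pc, pe, pb = chain[j]
                    cand = (pc + L, pe - d, pb - 1)
                if chain[i] is None or cand > chain[i]:
                    chain[i] = cand
                    back[i] = (j, ui, d)
    # best chain end, with the optional partial extension counted in coverage
    best_score = None
    best_end = None
    best_partial = None  # (unit_index, length, edits)
    for i in range(n + 1):
        if chain[i] is None:
            continue
        partial = _best_partial(seq, i, units, max_edits)
        plen = partial[1] if partial else 0
        cov, ne, nb = chain[i]
        cand = (cov + plen, ne - (partial[2] if partial else 0), nb)
        if best_score is None or cand > best_score:
            best_score, best_end, best_partial = cand, i, partial

    if best_end is None:
        dec = RepeatDecomposition(seq, left_flank=seq, low_coverage=True)
        return dec

    blocks: list[RepeatBlock] = []
    i = best_end
    while back[i] is not None:
        j, ui, d = back[i]
        blocks.append(RepeatBlock(units[ui].id, seq[j:i], d))
        i = j
        if chain[i] is None:
            break
    blocks.reverse()
    start = i
    partial_tail = None
    partial_seq = ""
    right_start = best_end
    if best_partial:
        ui, plen, pe = best_partial
        partial_tail = (units[ui].id, plen)
        partial_seq = seq[best_end: best_end + plen]
        right_start = best_end + plen
    dec = RepeatDecomposition(
        seq,
        blocks=blocks,
        partial_tail=partial_tail,
        partial_seq=partial_seq,
        left_flank=seq[:start],
        right_flank=seq[right_start:],
    )
    covered = sum(len(b.copy_seq) for b in blocks) + len(partial_seq)
    if covered < 0.5 * n:
        dec.low_coverage = True
    dec.polymorphic_sites = _polymorphic_sites(dec, units)
    return dec


def _best_partial(seq, i, units, max_edits):
    """Longest terminal partial unit starting at *i*: a >=50%-length
    consensus prefix within the edit budget."""
    best = None
    for ui, u in enumerate(units):
        max_len = min(len(seq) - i, u.length - 1)
        for plen in range(max_len, (u.length + 1) // 2 - 1, -1):
            if plen <= 0:
                break
            d = _edit_distance(seq[i: i + plen], u.consensus[:plen], max_edits)
            if d >= 0:
                cand = (plen, -d, -ui)
                if best is None or cand > best:
                    best = cand
                break  # longer is better; first hit per unit wins
    if best is None:
        return None
    plen, nd, nui = best
    return (-nui, plen, -nd)


def _polymorphic_sites(dec: RepeatDecomposition, units):
    """Offsets within each unit consensus where the copies disagree.

    Each copy (and the partial tail) is aligned to its consensus; the bases
    aligned to a consensus position, together with any following insertion,
    form that copy's allele at the position.  Sites with more than one
    observed allele are reported as (unit_id, offset, alleles).
    """
    by_unit = {u.id: u for u in units}
    alleles: dict[tuple[str, int], dict[str, int]] = {}
    items = [(b.unit_id, b.copy_seq, False) for b in dec.blocks]
    if dec.partial_tail:
        items.append((dec.partial_tail[0], dec.partial_seq, True))
    for uid, copy_seq, is_partial in items:
        cons = by_unit[uid].consensus
        target = cons[: len(copy_seq)] if is_partial else cons
        res = edlib.align(copy_seq, target, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, copy_seq, target)
        offset = -1
        per_offset: dict[int, str] = {}
        for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
            if tc != "-":
                offset += 1
                per_offset[offset] = "" if qc == "-" else qc
            elif offset >= 0:
                per_offset[offset] = per_offset.get(offset, "") + qc
        for off, allele in per_offset.items():
            d = alleles.setdefault((uid, off), {})
            d[allele] = d.get(allele, 0) + 1
    sites = []
    for (uid, off), obs in sorted(alleles.items()):
        if len(obs) > 1:
            sites.append((uid, off, tuple(sorted(obs))))
    return sites


def compare_decompositions(decomps: list[RepeatDecomposition]):
    """Copy-number heterogeneity and pattern distances across reads.

    Returns (per-unit stats dict, order strings, pairwise pattern edit
    distance matrix over block unit-id sequences).
    """
    import numpy as np

    if len(decomps) < 2:
        raise ValueError("need at least two decompositions to compare")
    unit_sets = [set(d.copy_counts()) for d in decomps]
    shared = set.intersection(*unit_sets)
    if not shared:
        raise ValueError("decompositions share no repeat unit types")
    all_units = sorted(set.union(*unit_sets))
    stats = {}
    for u in all_units:
        counts = [d.copy_counts().get(u, 0) for d in decomps]
        stats[u] = {
            "min": int(min(counts)),
            "max": int(max(counts)),
            "median": float(np.median(counts)),
        }
    orders = [d.order_string() for d in decomps]
    tokens = [[b.unit_id for b in d.blocks] for d in decomps]
    m = len(decomps)
    dist = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = _token_edit_distance(tokens[i], tokens[j])
    return stats, orders, dist


def _token_edit_distance(a: list[str], b: list[str]) -> int:
    prev = list(range(len(b) + 1))
    for i, ta in enumerate(a, 1):
        cur = [i]
        for j, tb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ta != tb))
            )
        prev = cur
    return prev[-1]
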