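"""Stowaway-like MITE discovery: structural scan and homology search.

Structural mode looks for the conserved terminal motif (default CTCCCT) and
its reverse complement downstream, extends the terminal inverted repeat
inward under a mismatch budget, and demands the TA target-site duplication
immediately outside both termini.  Homology mode is a k-mer seeded,
Smith-Waterman refined local search with the validation filters used for
BAC-end-sequence mining: TSD present, TIR detectable, enough flanking
sequence on both sides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from ._align import max_base_pairs, sw_align
from .sequences import GenomicSequence, IUPAC_EXPAND, revcomp

_COMPL = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MiningParams:
    terminal_motif: str = "CTCCCT"
    min_tir: int = 13
    max_tir: int = 30
    max_mismatch_per_tir: int = 2
    min_len: int = 80
    max_len: int = 600
    require_tsd: bool = True
    tsd: str = "TA"
    allow_gu_pairs: bool = False  # wobble pairs in the hairpin score

    def __post_init__(self) -> None:
        bad = set(self.terminal_motif) - set(IUPAC_EXPAND)
        if bad:
            raise ValueError(f"terminal_motif has non-IUPAC characters: {sorted(bad)}")


@dataclass
class TIRPair:
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    tir_length: int
    mismatches: int
    motif_matched: bool


@dataclass
class MITECandidate:
    sequence_id: str
    start: int
    end: int
    strand: str
    tsd: str | None
    tir: TIRPair
    at_content: float
    hairpin_score: float
    length: int
    source: str = "structural"
    seq: str = field(default="", repr=False)


@dataclass
class HomologyHit:
    sequence_id: str
    start: int
    end: int
    identity: float
    aligned_length: int
    left_flank_length: int
    right_flank_length: int
    validated: bool = False
    score: float = 0.0


def at_content(seq: str) -> float:
    """(A+T) / (A+C+G+T); N bases are excluded from both counts."""
    if not seq:
        raise ValueError("empty sequence")
    n_at = seq.count("A") + seq.count("T")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("sequence contains only N")
    return n_at / denom


def hairpin_score(seq: str, min_loop: int = 3, allow_gu: bool = False) -> float:
    """Fraction of the maximum possible base pairs realizable in a nested
    (hairpin-like) pairing: Nussinov max pairs / floor(len/2), in [0, 1]."""
    if len(seq) < 10:
        raise ValueError("sequence shorter than 10 bp")
    return max_base_pairs(seq, min_loop=min_loop, allow_gu=allow_gu) / (len(seq) // 2)


def _motif_regex(motif: str) -> re.Pattern:
    # N in the subject never satisfies a motif position
    parts = []
    for ch in motif:
        bases = "".join(sorted(IUPAC_EXPAND[ch]))
        parts.append(f"[{bases}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def _find_motif(residues: str, motif: str) -> list[int]:
    if set(motif) <= set("ACGT"):
        out, pos = [], residues.find(motif)
        while pos != -1:
            out.append(pos)
            pos = residues.find(motif, pos + 1)
        return out
    return [m.start() for m in _motif_regex(motif).finditer(residues)]


def _extend_tir(residues: str, start: int, end: int, max_tir: int,
                max_mismatch: int) -> tuple[int, int]:
    """Longest inverted-repeat extent from the termini inward.

    Returns (tir_length, mismatches); the TIR always ends on a matching
    column and carries at most ``max_mismatch`` mismatched columns.
    """
    limit = min(max_tir, (end - start) // 2)
    mm = 0
    best_len, best_mm = 0, 0
    for k in range(limit):
        lc = residues[start + k]
        rc = residues[end - 1 - k]
        match = lc in _COMPL and _COMPL[lc] == rc
        if not match:
            mm += 1
            if mm > max_mismatch:
                break
        else:
            best_len, best_mm = k + 1, mm
    return best_len, best_mm


def _scan_plus(residues: str, seq_id: str, params: MiningParams
               ) -> list[MITECandidate]:
    motif = params.terminal_motif.upper()
    starts = _find_motif(residues, motif)
    ends = [p + len(motif) for p in _find_motif(residues, revcomp(motif))]
    if not starts or not ends:
        return []
    out: list[MITECandidate] = []
    import bisect
    tsd = params.tsd
    t = len(tsd)
    for s in starts:
        lo = bisect.bisect_left(ends, s + params.min_len)
        hi = bisect.bisect_right(ends, s + params.max_len)
        for e in ends[lo:hi]:
            if params.require_tsd:
                if residues[s - t:s] != tsd or residues[e:e + t] != tsd:
                    continue
            tir_len, mm = _extend_tir(residues, s, e, params.max_tir,
                                      params.max_mismatch_per_tir)
            if tir_len < params.min_tir:
                continue
            el = residues[s:e]
            out.append(MITECandidate(
                sequence_id=seq_id, start=s, end=e, strand="+",
                tsd=tsd if residues[s - t:s] == tsd == residues[e:e + t] else None,
                tir=TIRPair(s, s + tir_len, e - tir_len, e, tir_len, mm, True),
                at_content=at_content(el),
                hairpin_score=hairpin_score(el, allow_gu=params.allow_gu_pairs),
                length=e - s, source="structural", seq=el))
    return out


def _resolve_overlaps(cands: list[MITECandidate]) -> list[MITECandidate]:
    """Keep the best of partially-overlapping candidates; strictly nested
    pairs are both retained (true nested insertions exist)."""
    order = sorted(cands, key=lambda c: (-c.tir.tir_length, c.tir.mismatches,
                                         -c.length, c.start, c.end))
    accepted: list[MITECandidate] = []
    for c in order:
        ok = True
        for a in accepted:
            overlap = c.start < a.end and a.start < c.end
            nested = ((c.start >= a.start and c.end <= a.end)
                      or (a.start >= c.start and a.end <= c.end))
            if overlap and not nested:
                ok = False
                break
        if ok:
            accepted.append(c)
    return sorted(accepted, key=lambda c: (c.sequence_id, c.start, c.end))


def find_tir_candidates(seq: GenomicSequence,
                        params: MiningParams | None = None
                        ) -> list[MITECandidate]:
    """Structural scan of one record for TSD/TIR-bounded candidates.

    Both strands are examined; because the element's right terminus is the
    reverse complement of its left, minus-strand hits map onto the same
    loci and are deduplicated, so reported candidates always carry the
    orientation in which the left TIR starts with the terminal motif
    (strand '+').
    """
    params = params or MiningParams()
    residues = seq.residues.upper()
    cands = _scan_plus(residues, seq.id, params)
    rc = revcomp(residues)
    L = len(residues)
    seen = {(c.start, c.end) for c in cands}
    for c in _scan_plus(rc, seq.id, params):
        s, e = L - c.end, L - c.start
        if (s, e) not in seen:
            seen.add((s, e))
            cands.append(replace(c, start=s, end=e,
                                 tir=TIRPair(s, s + c.tir.tir_length,
                                             e - c.tir.tir_length, e,
                                             c.tir.tir_length,
                                             c.tir.mismatches, True),
                                 seq=residues[s:e]))
    return _resolve_overlaps(cands)


def mine(sequences: list[GenomicSequence], params: MiningParams | None = None
         ) -> list[MITECandidate]:
    """Structural scan over many records (records are independent)."""
    out: list[MITECandidate] = []
    for s in sequences:
        out.extend(find_tir_candidates(s, params))
    return out


# ---------------------------------------------------------------------------
# homology search


@dataclass
class HomologyParams:
    word_size: int = 11
    min_identity: float = 0.6
    min_aligned_fraction: float = 0.5
    min_flank: int = 100  # used by validate_hit
    tir_slack: int = 5


def _alignment_identity(a: str, b: str, ai, bi) -> tuple[float, int]:
    matches = 0
    cols = 0
    for x, y in zip(ai, bi):
        if x >= 0 and y >= 0:
            cols += 1
            if a[x] == b[y] and a[x] != "N":
                matches += 1
    return (matches / cols if cols else 0.0), cols


def homology_search(query: str, database: list[GenomicSequence],
                    params: HomologyParams | None = None) -> list[HomologyHit]:
    """Seeded local search of a query consensus against a sequence set.

    Exact ``word_size``-mers seed candidate regions; each seeded region is
    refined with a local Smith-Waterman alignment restricted to a window
    around the seeds (identity/aligned-fraction thresholds take the place of
    BLAST e-values, which depend on database-size statistics).
    """
    params = params or HomologyParams()
    w = params.word_size
    if len(query) < w:
        raise ValueError("query shorter than word_size")
    query = query.upper()
    words: dict[str, list[int]] = {}
    for i in range(len(query) - w + 1):
        words.setdefault(query[i:i + w], []).append(i)
    hits: list[HomologyHit] = []
    for rec in database:
        subj = rec.residues.upper()
        # seed positions on the subject, clustered into candidate windows
        seed_pos: list[int] = []
        for j in range(len(subj) - w + 1):
            if subj[j:j + w] in words:
                seed_pos.append(j)
        if not seed_pos:
            continue
        windows: list[tuple[int, int]] = []
        margin = len(query)
        cur_lo = max(0, seed_pos[0] - margin)
        cur_hi = min(len(subj), seed_pos[0] + w + margin)
        for j in seed_pos[1:]:
            lo, hi = max(0, j - margin), min(len(subj), j + w + margin)
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                windows.append((cur_lo, cur_hi))
                cur_lo, cur_hi = lo, hi
        windows.append((cur_lo, cur_hi))
        for lo, hi in windows:
            score, ai, bi = sw_align(query, subj[lo:hi])
            if score <= 0:
                continue
            ident, cols = _alignment_identity(query, subj[lo:hi], ai, bi)
            s_idx = [y for y in bi if y >= 0]
            if not s_idx:
                continue
            if ident < params.min_identity:
                continue
            if cols < params.min_aligned_fraction * len(query):
                continue
            start, end = lo + s_idx[0], lo + s_idx[-1] + 1
            hits.append(HomologyHit(rec.id, start, end, ident, cols,
                                    left_flank_length=start,
                                    right_flank_length=len(subj) - end,
                                    score=score))
    return sorted(hits, key=lambda h: (h.sequence_id, h.start, h.end))


def validate_hit(hit: HomologyHit, database: list[GenomicSequence],
                 params: HomologyParams | None = None,
                 mining_params: MiningParams | None = None) -> HomologyHit:
    """Apply the BES-mining filters: TSD present, TIR pair detectable at the
    hit boundaries (within ``tir_slack`` bp), and both flanks long enough."""
    params = params or HomologyParams()
    rec = next((r for r in database if r.id == hit.sequence_id), None)
    if rec is None:
        raise ValueError(f"hit references unknown record {hit.sequence_id!r}")
    if not (0 <= hit.start < hit.end <= len(rec)):
        raise ValueError("hit coordinates outside the record")
    mp = mining_params or MiningParams()
    slack = params.tir_slack
    lo = max(0, hit.start - slack - 2)
    hi = min(len(rec), hit.end + slack + 2)
    window = rec.subseq(lo, hi)
    structural_ok = False
    # relax length bounds: the hit itself defines the expected span
    local = replace(mp, min_len=max(10, hit.end - hit.start - 2 * slack))
    for c in find_tir_candidates(window, local):
        if (abs((lo + c.start) - hit.start) <= slack
                and abs((lo + c.end) - hit.end) <= slack
                and c.tsd is not None):
            structural_ok = True
            break
    flanks_ok = (hit.left_flank_length >= params.min_flank
                 and hit.right_flank_length >= params.min_flank)
    return replace(hit, validated=structural_ok and flanks_ok)
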