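"""Local rearrangement analysis: nested insertions, pre-insertion
reconstruction, insertion-site genotyping and in-silico PCR.

The TA target-site duplication makes element history locally decodable: an
occupied site reads flank-TA-element-TA-flank, the ancestral empty site has
a single TA, an excision footprint leaves a short residual indel at the
junction, and abortive-gap-repair derivatives keep part of the element.
These signatures drive both the nested-insertion detector and the
locus-variant classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .families import global_align
from .miner import MITECandidate, MiningParams, find_tir_candidates
from .sequences import GenomicSequence, iupac_match, revcomp


class TSDAbsentError(ValueError):
    """No TA on both sides of the span: ancestral state not inferable."""


class LocusAnchorError(ValueError):
    """Flank anchors failed to align: observed sequence is the wrong locus."""


@dataclass
class NestedInsertion:
    outer: MITECandidate
    inner: MITECandidate          # coordinates relative to the outer span
    inner_family: str = "unknown"
    reconstructed_outer: str = ""


@dataclass
class LocusVariant:
    accession_id: str
    variant_class: str  # occupied|empty|footprint|internal_deletion|clustered|complex
    observed_length: int
    detail: str = ""


@dataclass
class PrimerSpec:
    name: str
    sequence: str  # 5' -> 3'
    max_mismatch: int = 2  # 3'-terminal 3 bases must always match exactly

    def __post_init__(self) -> None:
        if len(self.sequence) < 15:
            raise ValueError("primer shorter than 15 nt")
        self.sequence = self.sequence.upper().replace(" ", "")


@dataclass
class Amplicon:
    start: int
    end: int
    length: int
    sequence: str


def reconstruct_preinsertion(seq: str, element_start: int, element_end: int) -> str:
    """Excise [start-2, end): the element plus one TSD copy, keeping a single
    ancestral TA.  Requires TA immediately outside both termini."""
    if seq[max(0, element_start - 2):element_start] != "TA" \
            or seq[element_end:element_end + 2] != "TA":
        raise TSDAbsentError(
            "no TA target-site duplication flanking the span; "
            "cannot infer the ancestral state")
    return seq[:element_start - 2] + seq[element_end:]


@dataclass
class NestedScanParams:
    tsd_options: tuple[str, ...] = ("TA", "TTA")
    tir_margin: int = 0  # extra clearance beyond the outer TIRs


def detect_nested(candidate: MITECandidate, seq: GenomicSequence,
                  params: NestedScanParams | None = None,
                  mining_params: MiningParams | None = None
                  ) -> list[NestedInsertion]:
    """Re-run the structural scanner inside an outer candidate.

    Each TSD alternative (default TA plus the Tourist-style TTA) is tried;
    inner hits overlapping the outer TIRs are discarded.  For every inner
    hit the pre-nesting outer sequence is reconstructed by excising the
    inner span plus one TSD copy.
    """
    params = params or NestedScanParams()
    mp = mining_params or MiningParams()
    outer_seq = seq.residues[candidate.start:candidate.end]
    window = GenomicSequence(f"{candidate.sequence_id}|outer", outer_seq)
    out: list[NestedInsertion] = []
    lo = candidate.tir.tir_length + params.tir_margin
    hi = len(outer_seq) - candidate.tir.tir_length - params.tir_margin
    for tsd in params.tsd_options:
        for inner in find_tir_candidates(window, replace(mp, tsd=tsd)):
            if inner.start - len(tsd) < lo or inner.end + len(tsd) > hi:
                continue  # would overlap the outer TIRs
            if (inner.start, inner.end) == (0, len(outer_seq)):
                continue  # the outer element itself
            reconstructed = (outer_seq[:inner.start - len(tsd)]
                             + outer_seq[inner.end:])
            out.append(NestedInsertion(outer=candidate, inner=inner,
                                       reconstructed_outer=reconstructed))
    out.sort(key=lambda n: (n.inner.start, n.inner.end))
    return out


# ---------------------------------------------------------------------------
# locus-variant classification


@dataclass
class GenotypeParams:
    footprint_max: int = 10
    flank_anchor: int = 30
    anchor_min_identity: float = 0.90
    min_element_fraction: float = 0.90
    min_internal_gap: int = 20
    clustered_window: int = 100
    junction_window: int = 14  # footprint_max + TSD slack


def classify_locus_variant(reference_occupied: str,
                           element_span: tuple[int, int],
                           observed: GenomicSequence | str,
                           params: GenotypeParams | None = None,
                           accession_id: str = "",
                           mining_params: MiningParams | None = None
                           ) -> LocusVariant:
    """Assign one haplotype to a structural class at an insertion site.

    Decision rules, in order: (1) flank anchors of the reference must align
    in the observed haplotype (else :class:`LocusAnchorError`); (2) two or
    more structural candidates near the site -> ``clustered``; (3) one
    candidate covering >= ``min_element_fraction`` of the reference element
    -> ``occupied``; otherwise the observed haplotype is aligned to the
    reconstructed empty site: zero residual bases at the junction ->
    ``empty``, a 1..footprint_max bp residual indel -> ``footprint``, a
    larger insertion that aligns to the element with a contiguous gap or
    length deficit >= ``min_internal_gap`` -> ``internal_deletion``; anything
    else -> ``complex``.
    """
    params = params or GenotypeParams()
    obs = observed.residues if isinstance(observed, GenomicSequence) else observed
    acc = accession_id or (observed.id if isinstance(observed, GenomicSequence) else "")
    start, end = element_span
    element = reference_occupied[start:end]
    empty_ref = reconstruct_preinsertion(reference_occupied, start, end)
    junction = start - 2  # position of the single TA in the empty reference

    # structural candidates in the haplotype (also used below)
    cands = find_tir_candidates(
        GenomicSequence(acc or "obs", obs), mining_params or MiningParams())

    # (1) anchors, checked on the haplotype with detected elements excised —
    # an insertion may legitimately interrupt an anchor (clustered sites)
    stripped = obs
    excised: list[tuple[int, int]] = []
    # right-to-left so earlier coordinates stay valid; skip spans overlapping
    # an already-excised one (e.g. a chimeric candidate bridging two elements)
    for c in sorted(cands, key=lambda c: (-c.start, c.end - c.start)):
        if c.tsd is None:
            continue
        if any(c.start < e and s < c.end for s, e in excised):
            continue
        stripped = reconstruct_preinsertion(stripped, c.start, c.end)
        excised.append((c.start, c.end))
    left_anchor = reference_occupied[max(0, start - 2 - params.flank_anchor):start - 2]
    right_anchor = reference_occupied[end + 2:end + 2 + params.flank_anchor]
    for name, anchor in (("left", left_anchor), ("right", right_anchor)):
        if not anchor:
            raise LocusAnchorError(f"no {name} flank available in the reference")
        # a footprint may erode up to footprint_max junction-proximal bases
        need = params.anchor_min_identity * max(1, len(anchor) - params.footprint_max)
        matched = max(_anchor_matches(anchor, obs), _anchor_matches(anchor, stripped))
        if matched < need:
            raise LocusAnchorError(
                f"{name} flank anchor does not align in {acc or 'observed'} "
                f"(wrong locus?)")
    if len(cands) >= 2:
        gaps = [cands[i + 1].start - cands[i].end for i in range(len(cands) - 1)]
        if min(gaps) <= params.clustered_window:
            return LocusVariant(acc, "clustered", len(obs),
                                f"{len(cands)} elements, min gap {min(gaps)} bp")
    if len(cands) == 1 and cands[0].length >= params.min_element_fraction * len(element):
        return LocusVariant(acc, "occupied", len(obs),
                            f"element {cands[0].length} bp at {cands[0].start}")

    # (4) compare to the reconstructed empty site around the junction
    aln = global_align(obs, empty_ref)
    ins_run = del_run = 0
    ins_best = del_best = 0
    ref_pos = -1
    ins_at_junction = []
    w = max(params.junction_window, params.footprint_max + 4)
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if cb != "-":
            ref_pos += 1
        near = abs(ref_pos - junction) <= w
        if cb == "-" and ca != "-":
            ins_run += 1
            if near:
                ins_at_junction.append(ca)
        else:
            ins_best = max(ins_best, ins_run)
            ins_run = 0
        if ca == "-" and cb != "-":
            del_run += 1 if near else 0
        else:
            del_best = max(del_best, del_run)
            del_run = 0
    ins_best = max(ins_best, ins_run)
    del_best = max(del_best, del_run)
    inserted = len(ins_at_junction)
    residual = inserted + del_best

    if residual == 0:
        return LocusVariant(acc, "empty", len(obs), "matches ancestral site")
    if residual <= params.footprint_max:
        return LocusVariant(acc, "footprint", len(obs),
                            f"{inserted} bp inserted / {del_best} bp deleted "
                            f"at the junction")
    # large insertion at the junction: partial element (derivative)?
    segment = "".join(ins_at_junction)
    if len(segment) >= params.min_internal_gap:
        seg_aln = global_align(segment, element)
        gap = _max_internal_gap(seg_aln.aligned_a, seg_aln.aligned_b)
        deficit = len(element) - len(segment)
        if seg_aln.identity >= 0.7 and (gap >= params.min_internal_gap
                                        or deficit >= params.min_internal_gap):
            return LocusVariant(acc, "internal_deletion", len(obs),
                                f"{len(segment)} of {len(element)} bp retained")
        if seg_aln.identity >= 0.7 and deficit <= 0.1 * len(element):
            return LocusVariant(acc, "occupied", len(obs),
                                "full-length element (termini degraded)")
    return LocusVariant(acc, "complex", len(obs),
                        f"{inserted} bp inserted, unmatched structure")


def _anchor_matches(query: str, subject: str) -> int:
    """Matched bases in the best local alignment of query within subject."""
    from ._align import sw_align
    score, ai, bi = sw_align(query, subject)
    matches = 0
    for x, y in zip(ai, bi):
        if x >= 0 and y >= 0 and query[x] == subject[y]:
            matches += 1
    return matches


def _max_internal_gap(row_a: str, row_b: str) -> int:
    """Longest run of gaps in row_a opposite bases of row_b, ignoring end gaps."""
    core = row_a.strip("-")
    offset = len(row_a) - len(row_a.lstrip("-"))
    best = run = 0
    for i, c in enumerate(core):
        if c == "-" and row_b[offset + i] != "-":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


# ---------------------------------------------------------------------------
# in-silico PCR


@dataclass
class PCRParams:
    max_product: int = 5000
    max_mismatch: int = 2
    three_prime_exact: int = 3


def _binding_sites(template: str, primer: str, params: PCRParams
                   ) -> tuple[list[int], list[int]]:
    """Primer binding sites on both strands of the template.

    Returns (forward_starts, reverse_ends): forward sites extend rightward
    from ``start``; reverse sites extend leftward, ending the amplicon at
    ``end``.  IUPAC codes in the primer match their expansion; N in the
    template matches nothing.  The 3'-terminal bases must match exactly.
    """
    L = len(primer)
    fwd: list[int] = []
    rev: list[int] = []
    rc = revcomp(primer)
    k = params.three_prime_exact
    for p in range(len(template) - L + 1):
        window = template[p:p + L]
        mm = sum(0 if iupac_match(a, b) else 1 for a, b in zip(primer, window))
        if mm <= params.max_mismatch and all(
                iupac_match(a, b) for a, b in zip(primer[-k:], window[-k:])):
            fwd.append(p)
        mm = sum(0 if iupac_match(a, b) else 1 for a, b in zip(rc, window))
        if mm <= params.max_mismatch and all(
                iupac_match(a, b) for a, b in zip(rc[:k], window[:k])):
            rev.append(p + L)
    return fwd, rev


def insilico_pcr(template: GenomicSequence, fwd: PrimerSpec,
                 rev: PrimerSpec | None = None,
                 params: PCRParams | None = None) -> list[Amplicon]:
    """Predict amplicons from every convergent primer-site pair.

    Single-primer mode (``rev=None``) uses the same primer on both strands,
    reproducing TIR-anchored amplification of full-length elements.
    """
    params = params or PCRParams()
    t = template.residues.upper()
    f_f, f_r = _binding_sites(t, fwd.sequence, params)
    if rev is None:
        r_f, r_r = f_f, f_r
    else:
        r_f, r_r = _binding_sites(t, rev.sequence, params)
    fwd_sites = sorted(set(f_f) | set(r_f))
    rev_sites = sorted(set(f_r) | set(r_r))
    min_len = len(fwd.sequence) if rev is None else max(len(fwd.sequence),
                                                        len(rev.sequence))
    out = []
    for s in fwd_sites:
        for e in rev_sites:
            if e - s >= min_len and e - s <= params.max_product:
                out.append(Amplicon(s, e, e - s, t[s:e]))
    out.sort(key=lambda a: (a.start, a.end))
    return out


# ---------------------------------------------------------------------------
# polymorphism report


def polymorphism_report(variants_by_locus: dict[str, list[LocusVariant]]
                        ) -> pd.DataFrame:
    """Per-locus class counts, insertion-allele frequency and polymorphism
    flag (>= 2 classes observed).  Alleles carrying element material
    (occupied, internal_deletion, clustered) count toward the insertion
    frequency."""
    if not variants_by_locus:
        raise ValueError("need at least one locus")
    carrying = {"occupied", "internal_deletion", "clustered"}
    rows = []
    for locus, variants in sorted(variants_by_locus.items()):
        counts: dict[str, int] = {}
        for v in variants:
            counts[v.variant_class] = counts.get(v.variant_class, 0) + 1
        total = len(variants)
        freq = sum(n for c, n in counts.items() if c in carrying) / total
        row = {"locus": locus, "n": total,
               "insertion_frequency": freq,
               "polymorphic": len(counts) >= 2}
        for c in ("occupied", "empty", "footprint", "internal_deletion",
                  "clustered", "complex"):
            row[c] = counts.get(c, 0)
        rows.append(row)
    return pd.DataFrame(rows)
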