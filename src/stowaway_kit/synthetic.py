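"""Synthetic genomes with planted Stowaway-like elements and full ground truth.

The generator emulates the salient features of the host sequence context the
toolkit targets: AT-rich background, short (<500 bp) elements with 13-30 bp
terminal inverted repeats whose outermost 6 bp are the conserved CTCCCT
motif, a TA target-site duplication created on insertion, family-level
divergence among copies, nested insertions, excision footprints and
segregating presence/absence across accessions.  Every planted feature is
recorded in a :class:`SyntheticTruth` ledger so that mining, classification,
copy-number estimation and genotyping can all be scored without external
data.

Randomness: each operation takes an explicit integer seed and derives an
independent numpy Generator from it, so identical inputs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import GenomicSequence, revcomp

_BASES = np.frombuffer(b"ATCG", dtype=np.uint8)

VARIANT_CLASSES = ("intact", "internal_deletion", "footprint_only", "empty")
LOCUS_CLASSES = ("occupied", "empty", "footprint", "internal_deletion", "clustered")


@dataclass
class FamilySpec:
    """Parameters of one synthetic MITE family.

    ``at_fraction=None`` means "draw once from U[0.60, 0.72]" when the family
    is generated, mirroring the observed AT range of these elements.
    """

    family_id: str
    consensus_length: int = 274
    tir_length: int = 16
    terminal_motif: str = "CTCCCT"
    at_fraction: float | None = None
    divergence: float = 0.05
    indel_rate: float = 0.002

    def __post_init__(self) -> None:
        if not 0 < self.consensus_length < 600:
            raise ValueError("consensus_length must be in (0, 600)")
        if self.tir_length < len(self.terminal_motif):
            raise ValueError("tir_length must be >= terminal motif length")
        if 2 * self.tir_length >= self.consensus_length:
            raise ValueError("TIRs must not overlap: 2*tir_length < consensus_length")
        if not 0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")
        if self.at_fraction is not None and not 0 <= self.at_fraction <= 1:
            raise ValueError("at_fraction must be in [0, 1]")


@dataclass
class ElementCopy:
    """One concrete element sequence tagged with its family of origin."""

    family_id: str
    copy_id: str
    seq: str


@dataclass
class TruthRecord:
    sequence_id: str
    start: int  # 0-based, first base of element (TIRs included, TSD excluded)
    end: int    # half-open
    family_id: str
    copy_id: str
    nesting_parent: str | None = None
    variant_class: str = "intact"


@dataclass
class SyntheticTruth:
    """Ledger of planted insertions; coordinates refer to the emitted sequence."""

    records: list[TruthRecord] = field(default_factory=list)

    def for_sequence(self, sequence_id: str) -> list[TruthRecord]:
        return [r for r in self.records if r.sequence_id == sequence_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        frame = pd.DataFrame(
            rows,
            columns=["sequence_id", "start", "end", "family_id", "copy_id",
                     "nesting_parent", "variant_class"],
        )
        return frame

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame["nesting_parent"] = frame["nesting_parent"].fillna(".")
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SyntheticTruth":
        frame = pd.read_csv(path, sep="\t", dtype={"nesting_parent": str})
        records = []
        for row in frame.itertuples(index=False):
            parent = None if row.nesting_parent in (".", "nan", None) else row.nesting_parent
            records.append(TruthRecord(row.sequence_id, int(row.start), int(row.end),
                                       row.family_id, row.copy_id, parent,
                                       row.variant_class))
        return cls(records)


def generate_background(length: int, at_fraction: float, seed: int) -> GenomicSequence:
    """I.i.d. background with P(A)=P(T)=at_fraction/2, P(C)=P(G)=(1-at)/2."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < at_fraction < 1:
        raise ValueError("at_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([at_fraction / 2, at_fraction / 2,
                  (1 - at_fraction) / 2, (1 - at_fraction) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    return GenomicSequence(f"bg_seed{seed}", arr.tobytes().decode("ascii"),
                           f"synthetic background at={at_fraction}")


def _random_at_controlled(n: int, n_at: int, rng: np.random.Generator) -> str:
    """Random sequence of length n with exactly n_at A/T bases."""
    n_at = int(np.clip(n_at, 0, n))
    is_at = np.zeros(n, dtype=bool)
    is_at[rng.permutation(n)[:n_at]] = True
    at_choice = rng.integers(0, 2, size=n)
    out = np.where(is_at, np.where(at_choice == 0, ord("A"), ord("T")),
                   np.where(at_choice == 0, ord("C"), ord("G"))).astype(np.uint8)
    return out.tobytes().decode("ascii")


def mutate(seq: str, divergence: float, indel_rate: float,
           rng: np.random.Generator, protect_prefix: int = 6,
           protect_suffix: int = 6, indel_protect_prefix: int | None = None,
           indel_protect_suffix: int | None = None) -> str:
    """Apply i.i.d. substitutions and single-base indels.

    Substitutions are uniform over the three alternative bases; indels are
    single-base with equal insert/delete probability.  The first
    ``protect_prefix`` and last ``protect_suffix`` positions (the conserved
    terminal motifs) are immune to both.  ``indel_protect_prefix/suffix``
    optionally widen the indel-free terminal span (e.g. to the whole TIR,
    modelling copies whose termini stayed structurally intact), defaulting
    to the substitution-protected span.
    """
    n = len(seq)
    out: list[str] = []
    alphabet = "ACGT"
    ipp = protect_prefix if indel_protect_prefix is None else indel_protect_prefix
    ips = protect_suffix if indel_protect_suffix is None else indel_protect_suffix
    for idx, ch in enumerate(seq):
        protected = idx < protect_prefix or idx >= n - protect_suffix
        if protected:
            out.append(ch)
            continue
        c = ch
        if rng.random() < divergence:
            c = alphabet[(alphabet.index(ch) + 1 + rng.integers(0, 3)) % 4] \
                if ch in alphabet else ch
        if (idx < ipp or idx >= n - ips):
            out.append(c)
            continue
        if rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # delete this base
            out.append(c)
            out.append(alphabet[rng.integers(0, 4)])
        else:
            out.append(c)
    return "".join(out)


def generate_family(spec: FamilySpec, n_copies: int, seed: int,
                    indel_protect_tirs: bool = False
                    ) -> tuple[str, list[ElementCopy]]:
    """Build a family consensus and ``n_copies`` diverged copies.

    The consensus is left TIR + internal region + reverse complement of the
    left TIR; the left TIR begins with the terminal motif, so the consensus
    starts with it and ends with its reverse complement.  AT content of the
    non-motif positions is adjusted so the whole consensus hits the requested
    AT fraction.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    at = spec.at_fraction if spec.at_fraction is not None else rng.uniform(0.60, 0.72)
    motif = spec.terminal_motif
    m = len(motif)
    L = spec.consensus_length
    motif_at = sum(motif.count(c) for c in "AT") * 2  # motif + its revcomp
    n_free = L - 2 * m
    want_at = round(at * L) - motif_at
    tir_tail = _random_at_controlled(spec.tir_length - m,
                                     round((spec.tir_length - m) * at), rng)
    left_tir = motif + tir_tail
    interior_len = L - 2 * spec.tir_length
    # remaining AT budget after the TIR tail (counted twice: tail + its rc)
    tail_at = sum(tir_tail.count(c) for c in "AT") * 2
    interior = _random_at_controlled(interior_len, want_at - tail_at, rng)
    consensus = left_tir + interior + revcomp(left_tir)
    assert len(consensus) == L
    ip = spec.tir_length if indel_protect_tirs else m
    copies = [
        ElementCopy(spec.family_id, f"{spec.family_id}.{k}",
                    mutate(consensus, spec.divergence, spec.indel_rate, rng,
                           protect_prefix=m, protect_suffix=m,
                           indel_protect_prefix=ip, indel_protect_suffix=ip))
        for k in range(n_copies)
    ]
    return consensus, copies


def _ta_sites(residues: str, lo: int = 0, hi: int | None = None) -> list[int]:
    hi = len(residues) if hi is None else hi
    sites = []
    pos = residues.find("TA", lo)
    while pos != -1 and pos + 2 <= hi:
        sites.append(pos)
        pos = residues.find("TA", pos + 1)
    return sites


def plant_insertions(genome: GenomicSequence, elements: list[ElementCopy] | list[str],
                     n: int, seed: int, min_spacing: int = 100
                     ) -> tuple[GenomicSequence, SyntheticTruth]:
    """Insert ``n`` elements at TA sites, duplicating the target (TA -> TA
    element TA).  Elements are drawn from ``elements`` round-robin in genomic
    order; truth coordinates refer to the final mutated sequence.
    """
    elems = [e if isinstance(e, ElementCopy) else ElementCopy("el", f"el.{i}", e)
             for i, e in enumerate(elements)]
    if n > 0 and not elems:
        raise ValueError("no elements supplied")
    rng = np.random.default_rng(seed)
    sites_all = _ta_sites(genome.residues)
    order = rng.permutation(len(sites_all))
    chosen: list[int] = []
    if n > 0:
        for k in order:
            s = sites_all[k]
            if all(abs(s - c) >= max(min_spacing, 4) for c in chosen):
                chosen.append(s)
                if len(chosen) == n:
                    break
    if len(chosen) < n:
        raise ValueError(
            f"insufficient TA sites: needed {n}, found {len(chosen)} "
            f"with spacing >= {min_spacing}")
    chosen.sort()
    parts: list[str] = []
    truth = SyntheticTruth()
    prev = 0
    offset = 0
    for i, site in enumerate(chosen):
        el = elems[i % len(elems)]
        parts.append(genome.residues[prev:site + 2])  # up to and incl. the TA
        parts.append(el.seq)
        parts.append("TA")
        start = offset + site + 2
        truth.records.append(TruthRecord(genome.id, start, start + len(el.seq),
                                         el.family_id, f"p{i:05d}.{el.copy_id}"))
        offset += len(el.seq) + 2
        prev = site + 2
    parts.append(genome.residues[prev:])
    mutated = GenomicSequence(genome.id, "".join(parts), genome.description)
    return mutated, truth


def plant_nested(genome: GenomicSequence, truth: SyntheticTruth,
                 inner_element: ElementCopy | str, target_copy_id: str,
                 seed: int, tir_margin: int = 20
                 ) -> tuple[GenomicSequence, SyntheticTruth]:
    """Insert an element inside an existing intact planted copy (TA TSD).

    ``tir_margin`` keeps the inner insertion away from the outer TIRs so the
    outer element remains structurally recognizable.
    """
    inner = inner_element if isinstance(inner_element, ElementCopy) \
        else ElementCopy("inner", "inner.0", inner_element)
    target = next((r for r in truth.records if r.copy_id == target_copy_id), None)
    if target is None:
        raise ValueError(f"no truth record with copy_id {target_copy_id!r}")
    if target.variant_class != "intact":
        raise ValueError(f"target copy {target_copy_id!r} is not intact "
                         f"({target.variant_class})")
    rng = np.random.default_rng(seed)
    sites = _ta_sites(genome.residues, target.start + tir_margin,
                      target.end - tir_margin)
    if not sites:
        raise ValueError("target copy contains no internal TA site")
    site = sites[rng.integers(0, len(sites))]
    L = len(inner.seq)
    residues = (genome.residues[:site + 2] + inner.seq + "TA"
                + genome.residues[site + 2:])
    new_records = []
    for r in truth.records:
        r = dataclasses.replace(r)
        if r.sequence_id == genome.id:
            if r.start <= site < r.end:
                r.end += L + 2          # record containing the site stretches
            elif r.start > site:
                r.start += L + 2
                r.end += L + 2
        new_records.append(r)
    new_records.append(TruthRecord(genome.id, site + 2, site + 2 + L,
                                   inner.family_id, f"n.{inner.copy_id}",
                                   nesting_parent=target_copy_id))
    return (GenomicSequence(genome.id, residues, genome.description),
            SyntheticTruth(new_records))


@dataclass
class LocusAccession:
    accession_id: str
    haplotype: GenomicSequence
    true_class: str


def simulate_locus_population(locus_flanks: tuple[str, str], element: str,
                              class_frequencies: dict[str, float],
                              n_accessions: int, seed: int,
                              second_element: str | None = None,
                              footprint_max: int = 10,
                              clustered_window: int = 100
                              ) -> list[LocusAccession]:
    """Per-accession haplotypes at one insertion site with known classes.

    occupied: flank + TA element TA + flank; empty: flank + TA + flank;
    footprint: empty site with a 1..footprint_max bp residual indel at the
    junction; internal_deletion: occupied with a contiguous deletion of
    20-80 % of the element (the deletion may remove a TIR terminus — only the
    class label is guaranteed); clustered: occupied plus a second element
    planted at a TA within ``clustered_window`` bp upstream.
    """
    bad = set(class_frequencies) - set(LOCUS_CLASSES)
    if bad:
        raise ValueError(f"unknown locus classes: {sorted(bad)}")
    total = sum(class_frequencies.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class frequencies sum to {total}, expected 1")
    fl, fr = locus_flanks
    rng = np.random.default_rng(seed)
    classes = list(class_frequencies)
    probs = np.array([class_frequencies[c] for c in classes])
    el2 = second_element if second_element is not None else element
    out: list[LocusAccession] = []
    for i in range(n_accessions):
        cls = classes[rng.choice(len(classes), p=probs)]
        if cls == "occupied":
            hap = fl + "TA" + element + "TA" + fr
        elif cls == "empty":
            hap = fl + "TA" + fr
        elif cls == "footprint":
            k = int(rng.integers(1, footprint_max + 1))
            if rng.random() < 0.5:  # residual insertion
                extra = "".join("ACGT"[b] for b in rng.integers(0, 4, k))
                hap = fl + "TA" + extra + fr
            else:                   # residual deletion across the junction
                empty = fl + "TA" + fr
                start = len(fl) + 2 - k // 2
                hap = empty[:start] + empty[start + k:]
        elif cls == "internal_deletion":
            frac = rng.uniform(0.2, 0.8)
            dlen = max(20, round(frac * len(element)))
            dstart = int(rng.integers(0, len(element) - dlen + 1))
            trunc = element[:dstart] + element[dstart + dlen:]
            hap = fl + "TA" + trunc + "TA" + fr
        elif cls == "clustered":
            sites = [s for s in _ta_sites(fl, max(0, len(fl) - clustered_window))
                     if s + 2 <= len(fl) - 4]
            if not sites:
                raise ValueError("left flank has no TA site inside the "
                                 "clustered window")
            s = sites[rng.integers(0, len(sites))]
            hap = (fl[:s] + "TA" + el2 + "TA" + fl[s + 2:]
                   + "TA" + element + "TA" + fr)
        else:  # pragma: no cover
            raise AssertionError(cls)
        out.append(LocusAccession(f"acc{i:04d}",
                                  GenomicSequence(f"acc{i:04d}", hap), cls))
    return out


def mining_panel(seed: int, n_genomes: int = 10, genome_length: int = 500_000,
                 n_elements_total: int = 200, max_divergence: float = 0.05
                 ) -> list[tuple[GenomicSequence, SyntheticTruth]]:
    """Standard structural-mining recovery panel.

    ``n_genomes`` AT-rich backgrounds, each carrying its share of
    ``n_elements_total`` planted copies drawn from three families with
    per-family divergence in [0.01, max_divergence] and structurally intact
    termini (TIRs free of indels; substitutions beyond the motif allowed).
    """
    rng = np.random.default_rng(seed)
    per_genome = n_elements_total // n_genomes
    panel = []
    for g in range(n_genomes):
        sub = int(rng.integers(0, 2**31 - 1))
        bg = generate_background(genome_length, float(rng.uniform(0.55, 0.70)), sub)
        elements: list[ElementCopy] = []
        for f in range(3):
            spec = FamilySpec(
                f"fam{g}.{f}",
                consensus_length=int(rng.integers(150, 401)),
                divergence=float(rng.uniform(0.01, max_divergence)),
                indel_rate=0.002,
            )
            _, copies = generate_family(spec, max(1, per_genome // 3 + 1),
                                        int(rng.integers(0, 2**31 - 1)),
                                        indel_protect_tirs=True)
            elements.extend(copies)
        genome, truth = plant_insertions(bg, elements, per_genome,
                                         int(rng.integers(0, 2**31 - 1)))
        genome.id = f"panel{g}"
        for r in truth.records:
            r.sequence_id = genome.id
        panel.append((genome, truth))
    return panel


def fragment_into_clones(genome: GenomicSequence, truth: SyntheticTruth,
                         clone_size: int, n_clones: int, seed: int
                         ) -> tuple[list[GenomicSequence], list[int]]:
    """Uniform random substrings emulating a BAC library; returns clones and
    the number of intact planted elements fully contained in each."""
    if clone_size > len(genome):
        raise ValueError("clone_size exceeds genome length")
    rng = np.random.default_rng(seed)
    intact = [(r.start, r.end) for r in truth.for_sequence(genome.id)
              if r.variant_class == "intact"]
    clones: list[GenomicSequence] = []
    counts: list[int] = []
    for i in range(n_clones):
        s = int(rng.integers(0, len(genome) - clone_size + 1))
        clones.append(genome.subseq(s, s + clone_size, f"{genome.id}_clone{i:04d}"))
        counts.append(sum(1 for a, b in intact if a >= s and b <= s + clone_size))
    return clones, counts
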