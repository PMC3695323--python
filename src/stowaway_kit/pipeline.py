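"""End-to-end pipeline: simulate -> mine -> classify -> copy-number -> nested.

Every stage logs its parameters and derived seed into ``run_log.json`` so any
artifact can be regenerated; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import copynumber, families, io, miner, structure, synthetic


def run_pipeline(config: io.PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run all stages; returns a summary dict (also written as JSON)."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config), "stages": {}}
    rng = np.random.default_rng(config.seed)

    # --- simulate -----------------------------------------------------------
    sim = config.simulate
    bg_seed = int(rng.integers(0, 2**31 - 1))
    background = synthetic.generate_background(sim.genome_length,
                                               sim.at_fraction, bg_seed)
    per_family: list[list[synthetic.ElementCopy]] = []
    consensi: list[tuple[str, str]] = []
    for f in range(sim.n_families):
        spec = synthetic.FamilySpec(
            f"simfam{f + 1}", consensus_length=sim.consensus_length,
            tir_length=sim.tir_length, terminal_motif=sim.terminal_motif,
            divergence=sim.divergence, indel_rate=sim.indel_rate)
        fam_seed = int(rng.integers(0, 2**31 - 1))
        cons, copies = synthetic.generate_family(spec, sim.copies_per_family,
                                                 fam_seed)
        consensi.append((spec.family_id, cons))
        per_family.append(copies)
    # interleave families so every family is represented among the insertions
    elements = [fam[k] for k in range(sim.copies_per_family)
                for fam in per_family]
    plant_seed = int(rng.integers(0, 2**31 - 1))
    genome, truth = synthetic.plant_insertions(background, elements,
                                               sim.n_insertions, plant_seed,
                                               min_spacing=sim.min_spacing)
    io.write_fasta([genome], out / "genome.fasta")
    truth.to_tsv(out / "truth.tsv")
    log["stages"]["simulate"] = {"seeds": [bg_seed, plant_seed],
                                 "planted": len(truth.records)}

    # --- mine ---------------------------------------------------------------
    mp = miner.MiningParams(
        terminal_motif=config.mine.terminal_motif, min_tir=config.mine.min_tir,
        max_tir=config.mine.max_tir,
        max_mismatch_per_tir=config.mine.max_mismatch_per_tir,
        min_len=config.mine.min_len, max_len=config.mine.max_len,
        require_tsd=config.mine.require_tsd)
    candidates = miner.mine([genome], mp)
    io.write_gff3(candidates, out / "candidates.gff3")
    io.write_bed(candidates, out / "candidates.bed")
    io.candidates_to_fasta(candidates, out / "elements.fasta")
    truth_spans = {(r.start, r.end) for r in truth.records}
    found_spans = {(c.start, c.end) for c in candidates}
    log["stages"]["mine"] = {
        "candidates": len(candidates),
        "recall": len(truth_spans & found_spans) / len(truth_spans)
        if truth_spans else None,
        "precision": len(truth_spans & found_spans) / len(found_spans)
        if found_spans else None,
    }

    # --- classify -----------------------------------------------------------
    element_list = [(f"mite{i:05d}", c.seq) for i, c in enumerate(
        sorted(candidates, key=lambda c: (c.sequence_id, c.start, c.end)))]
    cp = families.ClusterParams(config.classify.min_identity,
                                config.classify.min_coverage,
                                config.classify.min_length)
    fams = families.cluster_families(element_list, cp) if element_list else []
    io.families_to_tsv(fams, out / "families.tsv")
    io.write_named_fasta([(f.family_id, f.consensus) for f in fams],
                         out / "consensus.fasta")
    if len(fams) >= 2:
        dm = families.k2p_matrix([(f.family_id, f.consensus) for f in fams])
        tree = families.neighbor_joining(dm)
        (out / "families.nwk").write_text(tree.to_newick() + "\n")
    tir_entries = []
    by_id = dict(element_list)
    for f in fams:
        member_cand = next(c for i, c in enumerate(
            sorted(candidates, key=lambda c: (c.sequence_id, c.start, c.end)))
            if f.member_ids and f"mite{i:05d}" == f.member_ids[0])
        tir_entries.append((f.family_id,
                            by_id[f.member_ids[0]][:member_cand.tir.tir_length]))
    if tir_entries:
        tc = families.tir_consensus(tir_entries)
        with open(out / "tir_consensus.tsv", "w") as fh:
            for fid, tir in zip(tc.family_ids, tc.tirs):
                fh.write(f"{fid}\t{tir}\n")
            fh.write(f"consensus\t{tc.consensus}\n")
            fh.write(f"conserved_terminal_run\t{tc.conserved_terminal_run}\n")
    log["stages"]["classify"] = {"families": len(fams)}

    # --- copy number (simulated clone screen + configured screen) -----------
    clone_bp = int(config.screen.clone_size_mbp * 1e6)
    n_clones = min(config.screen.n_clones, 500)
    screen_log: dict = {}
    if clone_bp <= len(genome):
        clone_seed = int(rng.integers(0, 2**31 - 1))
        clones, counts = synthetic.fragment_into_clones(
            genome, truth, clone_bp, n_clones, clone_seed)
        positive = sum(1 for clone in clones
                       if miner.find_tir_candidates(clone, mp))
        sim_screen = copynumber.BACScreenResult(
            n_clones, positive, clone_bp / 1e6, len(genome) / 1e6)
        if 0 < positive < n_clones:
            est = copynumber.estimate(sim_screen, "poisson",
                                      config.screen.ci_level)
        else:
            est = copynumber.estimate(sim_screen, "naive",
                                      config.screen.ci_level
                                      if positive else None)
        screen_log["simulated"] = {
            "n_clones": n_clones, "n_positive": positive,
            "copies": est.copies, "density_per_mbp": est.density,
            "true_elements": len(truth.records)}
    log["stages"]["copy_number"] = screen_log

    # --- nested insertions --------------------------------------------------
    nested_rows = []
    for c in candidates:
        for n in structure.detect_nested(c, genome):
            nested_rows.append({
                "outer": f"{c.sequence_id}:{c.start}-{c.end}",
                "inner_start": c.start + n.inner.start,
                "inner_end": c.start + n.inner.end})
    with open(out / "nested.tsv", "w") as fh:
        fh.write("outer\tinner_start\tinner_end\n")
        for row in nested_rows:
            fh.write(f"{row['outer']}\t{row['inner_start']}\t{row['inner_end']}\n")
    log["stages"]["nested"] = {"nested_insertions": len(nested_rows)}

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
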