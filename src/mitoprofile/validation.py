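"""Replication and validation harness.

Recomputes, from the package's own machinery, the desk-scale quantities of
the published *M. flexura* mitogenome profile (organization arithmetic,
composition/skews, RSCU) and the synthetic validation studies
(plant-and-recover, likelihood oracle, topology recovery + bootstrap).
Everything here is derived at run time; the only stored inputs are the
transcribed published tables shipped as package data.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import io as mio
from .align import Alignment, concatenate
from .codon_usage import rscu_from_counts
from .composition import skews
from .control_region import (
    find_microsatellites,
    find_poly_runs,
    find_stem_loops,
    find_tandem_repeats,
)
from .organization import check_circle_conservation, feature_size, junction_gaps
from .phylogeny import (
    PhyloModel,
    bootstrap,
    fit,
    loglik,
    nj_tree,
    nni_search,
    simulate,
    transition_matrix,
)
from .rna_structure import FoldFailure, fold_cloverleaf, pair_stats
from .synthetic import (
    DEFAULT_TREE_NEWICK,
    GenomeConfig,
    SimConfig,
    default_truth_model,
    evolve_alignment,
    generate_mitogenome,
)
from .tree import _canon, from_newick

# ---------------------------------------------------------------------------
# published-table arithmetic
# ---------------------------------------------------------------------------


def organization_summary() -> dict:
    """Recompute every coordinate-derivable number of the published
    organization table and compare with the printed Size/IGN columns."""
    table = mio.load_reference_features()
    printed = mio.load_reference_printed()
    report = junction_gaps(table)
    size_mismatches = []
    ign_mismatches = []
    for f in table:
        size = feature_size(f, table.genome_length)
        if size != printed[f.name]["size"]:
            size_mismatches.append((f.name, size, printed[f.name]["size"]))
        ign = report.ign_of(f.name)
        if ign != printed[f.name]["ign"]:
            ign_mismatches.append((f.name, ign, printed[f.name]["ign"]))
    trna_sizes = [feature_size(f, table.genome_length) for f in table.by_class("tRNA")]
    starts = [printed[f.name]["start_codon"] for f in table.by_class("PCG")]
    stops = [printed[f.name]["stop_codon"] for f in table.by_class("PCG")]
    return {
        "genome_length": table.genome_length,
        "n_features": len(table),
        "n_pcg": len(table.by_class("PCG")),
        "n_trna": len(table.by_class("tRNA")),
        "n_rrna": len(table.by_class("rRNA")),
        "cr_length": feature_size(table["CR"], table.genome_length),
        "size_mismatches": size_mismatches,
        "ign_mismatches": ign_mismatches,
        "overlap_total": report.overlap_total,
        "overlap_junctions": report.overlap_count,
        "longest_overlap": report.longest_overlap,
        "spacer_total": report.spacer_total,
        "spacer_junctions": report.spacer_count,
        "trna_min": min(trna_sizes),
        "trna_max": max(trna_sizes),
        "start_atn": sum(s.startswith("AT") for s in starts),
        "start_att": starts.count("ATT"),
        "start_atg": starts.count("ATG"),
        "start_gtg": starts.count("GTG"),
        "start_ttg": starts.count("TTG"),
        "stop_taa": stops.count("TAA"),
        "stop_tag": stops.count("TAG"),
        "stop_incomplete_t": stops.count("T-"),
        "circle_conservation": check_circle_conservation(table),
    }


def composition_summary() -> dict:
    """Skews recomputed from the printed rounded percentages vs the printed
    skews, with the exact rounding-propagation bound per cell (each printed
    percentage carries +/-0.05 of rounding; the skew's worst-case error from
    two such percentages is 0.1/denominator, plus 0.0005 for the printed
    skew's own 3-decimal rounding)."""
    rows = []
    for r in mio.load_reference_composition():
        at, gc = skews(r["pct_A"], r["pct_T"], r["pct_G"], r["pct_C"])
        at_den = r["pct_A"] + r["pct_T"]
        gc_den = r["pct_G"] + r["pct_C"]
        rows.append(
            {
                "label": r["label"],
                "at_sum_delta": abs(r["pct_A"] + r["pct_T"] - r["at_content"]),
                "at_skew_delta": abs(at - r["at_skew"]),
                "gc_skew_delta": abs(gc - r["gc_skew"]),
                "at_skew_bound": 0.1 / at_den + 0.0005,
                "gc_skew_bound": 0.1 / gc_den + 0.0005,
            }
        )
    whole = next(r for r in mio.load_reference_composition() if r["label"] == "whole")
    at_whole, gc_whole = skews(whole["pct_A"], whole["pct_T"], whole["pct_G"], whole["pct_C"])
    return {
        "rows": rows,
        "max_at_sum_delta": max(r["at_sum_delta"] for r in rows),
        "whole_at_skew": round(at_whole, 3),
        "whole_gc_skew": round(gc_whole, 3),
        "whole_at_content": whole["pct_A"] + whole["pct_T"],
        "cr_at_content": next(
            r["pct_A"] + r["pct_T"] for r in mio.load_reference_composition() if r["label"] == "CR"
        ),
    }


def rscu_summary() -> dict:
    """RSCU from the transcribed published codon counts, checked against an
    inline arithmetic oracle (count * k / family total) and the family-mean
    normalization identity."""
    counts = mio.load_reference_codon_counts()
    table = rscu_from_counts(counts)
    code = table.code
    # independent arithmetic oracle, straight from count dictionaries
    max_oracle_diff = 0.0
    max_family_mean_dev = 0.0
    for aa, family in code.families.items():
        total = sum(counts.get(c, 0) for c in family)
        if total == 0:
            continue
        k = len(family)
        for c in family:
            oracle = counts.get(c, 0) * k / total
            max_oracle_diff = max(max_oracle_diff, abs(oracle - table.rscu[c]))
        mean = sum(table.rscu[c] for c in family) / k
        max_family_mean_dev = max(max_family_mean_dev, abs(mean - 1.0))
    leu = code.families["L"]
    leu_total = sum(counts[c] for c in leu)
    return {
        "total_codons": table.total(),
        "leu_family_size": len(leu),
        "ser_family_size": len(code.families["S"]),
        "leu_total": leu_total,
        "rscu_tta": table.rscu["TTA"],
        "rscu_tta_oracle": counts["TTA"] * len(leu) / leu_total,
        "max_oracle_diff": max_oracle_diff,
        "max_family_mean_dev": max_family_mean_dev,
        "top_codons": table.top_codons(5),
    }


# ---------------------------------------------------------------------------
# plant-and-recover
# ---------------------------------------------------------------------------

_ELEMENT_KEYS = {
    "tandem_repeat": ("unit_length", "copies"),
    "microsatellite": ("unit", "copies"),
    "poly_run": ("base", "run_length"),
    "stem_loop": ("stem_length", "loop_length", "mismatches", "flank_motif"),
}

_SCANNERS = {
    "tandem_repeat": find_tandem_repeats,
    "microsatellite": find_microsatellites,
    "poly_run": find_poly_runs,
    "stem_loop": find_stem_loops,
}


def recover_cr_elements(genome, table, truth) -> list:
    """Misses: planted CR elements not recovered exactly (span + details)."""
    f = table["CR"]
    seq = f.coding_sequence(genome)
    found = {kind: scan(seq, origin=f.start) for kind, scan in _SCANNERS.items()}
    misses = []
    for e in truth["cr_elements"]:
        hits = [x for x in found[e["kind"]] if (x.start, x.end) == (e["start"], e["end"])]
        if not hits or any(hits[0].details[k] != e[k] for k in _ELEMENT_KEYS[e["kind"]]):
            misses.append(e)
    return misses


def plant_recover_summary(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Exact recovery of every planted feature over ``n_seeds`` genomes:
    CR elements, ATGNTAA overlap motifs, planted overlap IGNs, tRNA
    G-U/mismatch pairs (via truth structures), plus fold heuristic quality."""
    element_planted = element_missed = 0
    motif_ok = motif_total = 0
    pair_planted = pair_missed = 0
    overlap_totals = []
    fold_total = fold_exact = fold_failures = dhu_correct = 0
    for s in range(base_seed, base_seed + n_seeds):
        genome, table, truth = generate_mitogenome(GenomeConfig(seed=s))
        misses = recover_cr_elements(genome, table, truth)
        element_planted += len(truth["cr_elements"])
        element_missed += len(misses)
        for m in truth["motif_junctions"]:
            motif_total += 1
            motif_ok += bool(m["matches_ATGNTAA"])
        overlap_totals.append(junction_gaps(table).overlap_total)
        for name, structure in truth["trna_structures"].items():
            seq = table[name].coding_sequence(genome)
            stats = pair_stats(seq, structure)
            for arm, _k, kind in truth["trna_planted_pairs"].get(name, []):
                pair_planted += 1
                a = stats.per_arm[arm]
                got = a["gu"] if kind == "GU" else a["mismatch"].get(kind, 0)
                if got < 1:
                    pair_missed += 1
            fold_total += 1
            try:
                fs = fold_cloverleaf(seq, table[name].anticodon, name=name)
            except FoldFailure:
                fold_failures += 1
                continue
            dhu_correct += fs.dhu_present == structure.dhu_present
            fold_exact += fs.arms == structure.arms
    return {
        "n_seeds": n_seeds,
        "elements_planted": element_planted,
        "elements_missed": element_missed,
        "motif_junctions_ok": motif_ok,
        "motif_junctions_total": motif_total,
        "overlap_total_each_seed": sorted(set(overlap_totals)),
        "trna_pairs_planted": pair_planted,
        "trna_pairs_missed": pair_missed,
        "fold_total": fold_total,
        "fold_arm_exact_fraction": fold_exact / fold_total,
        "fold_failures": fold_failures,
        "dhu_correct_fraction": dhu_correct / fold_total,
    }


# ---------------------------------------------------------------------------
# likelihood oracle
# ---------------------------------------------------------------------------


def brute_force_loglik(tree, aln: Alignment, model: PhyloModel) -> float:
    """Independent oracle: explicit summation over all internal-state
    assignments and rate categories (viable for <=4 taxa, short alignments)."""
    eig = model.eigensystem()
    rates = model.category_rates()
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    code = {b: i for i, b in enumerate("ACGT")}
    total = 0.0
    pmats = {}

    def pmat(length, rate):
        key = (length, rate)
        if key not in pmats:
            pmats[key] = transition_matrix(eig, rate * length)
        return pmats[key]

    for site in range(aln.length):
        obs = {n.name: aln[n.name][site] for n in nodes if n.is_leaf}
        states = {v for v in obs.values() if v in code}
        inv = model.freqs[code[next(iter(states))]] if len(states) == 1 else (
            1.0 if not states else 0.0
        )
        var = 0.0
        for r in rates:
            for assign in itertools.product(range(4), repeat=len(internal)):
                amap = dict(zip((id(n) for n in internal), assign))
                p = model.freqs[amap[id(tree.root)]]
                for n in nodes:
                    if n is tree.root:
                        continue
                    pm = pmat(n.length, r)
                    ps = amap[id(n.parent)]
                    if n.is_leaf:
                        b = obs[n.name]
                        p *= pm[ps].sum() if b not in code else pm[ps, code[b]]
                    else:
                        p *= pm[ps, amap[id(n)]]
                var += p
        var /= len(rates)
        total += float(np.log(model.p_inv * inv + (1 - model.p_inv) * var))
    return total


def likelihood_oracle_summary(seed: int = 1) -> dict:
    """Pruning vs brute-force enumeration on a 4-taxon/30-site problem, and
    the alpha -> infinity, p_inv = 0 single-rate limit."""
    rng = np.random.default_rng(seed)
    tree = from_newick("((A:0.12,B:0.31):0.14,C:0.23,D:0.08);")
    model = PhyloModel(
        freqs=np.array([0.31, 0.19, 0.16, 0.34]),
        exch=np.array([1.4, 5.0, 1.1, 0.9, 6.0, 1.0]),
        p_inv=0.15,
        alpha=0.6,
    )
    aln = simulate(tree, model, 30, rng)
    seqs = dict(aln.sequences)
    seqs["A"] = seqs["A"][:4] + "-N" + seqs["A"][6:]  # exercise missing data
    aln = Alignment(seqs)
    oracle_diff = abs(loglik(tree, aln, model) - brute_force_loglik(tree, aln, model))
    big_alpha = PhyloModel(freqs=model.freqs, exch=model.exch, p_inv=0.0, alpha=1e8)
    single = PhyloModel(freqs=model.freqs, exch=model.exch, p_inv=0.0, alpha=1.0, k=1)
    limit_diff = abs(loglik(tree, aln, big_alpha) - loglik(tree, aln, single))
    return {"oracle_diff": oracle_diff, "limit_diff": limit_diff, "n_sites": aln.length}


# ---------------------------------------------------------------------------
# topology recovery + bootstrap
# ---------------------------------------------------------------------------


def _sim_supermatrix(n_sites: int, seed: int) -> Alignment:
    lengths = {
        gene: n_sites // 13 + (1 if i < n_sites % 13 else 0)
        for i, gene in enumerate(
            ["ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3",
             "ND5", "ND4", "ND4L", "ND6", "CytB", "ND1"]
        )
    }
    alns, _ = evolve_alignment(SimConfig(seed=seed, gene_lengths=lengths))
    return concatenate(alns)


def topology_recovery_summary(
    n_replicates: int = 20,
    n_sites: int = 5000,
    b: int = 100,
    seed: int = 1,
) -> dict:
    """Simulate ``n_replicates`` supermatrices under the 14-taxon truth tree
    (GTR+I+G), re-infer each by NJ + model fit + NNI, and score generating-
    topology recovery; then bootstrap the first replicate (B = ``b``) and
    average the support of the true splits."""
    truth_splits = from_newick(DEFAULT_TREE_NEWICK).splits()
    rng = np.random.default_rng(seed)
    rep_seeds = [int(x) for x in rng.integers(0, 2**31 - 1, size=n_replicates)]
    recovered = 0
    alphas = []
    first = None
    for rs in rep_seeds:
        sup = _sim_supermatrix(n_sites, rs)
        start = nj_tree(sup)
        result = fit(start, sup, max_rounds=2)
        tree, _ = nni_search(result.tree, sup, result.model)
        alphas.append(result.model.alpha)
        if tree.splits() == truth_splits:
            recovered += 1
        if first is None:
            first = (sup, result.model, tree)
    sup, model, tree = first
    bt = bootstrap(sup, model, b=b, seed=int(rng.integers(0, 2**31 - 1)), tree=tree)
    support = {}
    _collect_supports(bt, support)
    true_supports = [support[s] for s in truth_splits if s in support]
    return {
        "n_replicates": n_replicates,
        "n_sites": n_sites,
        "recovered": recovered,
        "recovery_fraction": recovered / n_replicates,
        "alpha_estimates": [round(a, 3) for a in alphas],
        "truth_alpha": default_truth_model().alpha,
        "bootstrap_b": b,
        "n_true_splits": len(truth_splits),
        "n_true_splits_in_ml_tree": len(true_supports),
        "mean_true_split_support": float(np.mean(true_supports)) if true_supports else 0.0,
    }


def _collect_supports(tree, out: dict) -> None:
    all_taxa = frozenset(tree.taxa())
    below = {}
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = frozenset([n.name])
            continue
        below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
        if n.support is not None:
            side = below[id(n)]
            out[_canon(side, all_taxa - side)] = n.support
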