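"""Replication experiments on synthetic data.

Each function here sets up one seeded study condition (a planted-truth
transcriptome, a tandem-repeat spidroin family, an additive distance matrix),
runs the corresponding analysis end to end, and reports summary metrics
against the construction truth.  These drive both the package's verification
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import curation, phylo, repeat_arch
from .seq_io import parse_trinity_id
from .synth import (
    CTERM_TEMPLATE,
    NTERM_TEMPLATE,
    TranscriptomeSpec,
    acsp1_like_spec,
    boundary_fixture,
    make_spidroin,
    make_transcriptome,
    pflag_like_spec,
)


def _curate(fixture, params=None):
    fwd = curation.parse_hit_rows(fixture.forward_rows, fixture.subject_lengths)
    rev_lengths = {r.id: len(r) for r in fixture.records}
    rev = curation.parse_hit_rows(fixture.reverse_rows, rev_lengths)
    return curation.run_curation(
        fixture.records, fwd, rev, fixture.expression, fixture.rna_ids, params
    )


def trtap_truth_agreement(seed: int) -> dict[str, float]:
    """Run the full pruning pipeline on a 200-transcript / 60-gene planted
    fixture and compare every final call with the construction truth."""
    fixture = make_transcriptome(TranscriptomeSpec(seed=seed))
    result = _curate(fixture)
    truth = fixture.truth.set_index("transcript_id")
    calls = result.calls_frame().set_index("transcript_id")
    merged = truth.join(calls, lsuffix="_truth")
    disagreements = int(
        (
            (merged["category_truth"] != merged["category"])
            | (merged["reason_truth"] != merged["reason"])
        ).sum()
    )
    per_gene: dict[str, int] = {}
    for c in result.calls:
        if c.category != "DISCARD":
            g = parse_trinity_id(c.transcript_id).gene
            per_gene[g] = per_gene.get(g, 0) + 1
    return {
        "disagreements": disagreements,
        "total_calls": result.report.total,
        "n_transcripts": len(fixture.records),
        "max_retained_per_gene": max(per_gene.values()) if per_gene else 0,
    }


def boundary_behaviour(seed: int) -> dict[str, float]:
    """Classify the six transcripts planted exactly at the coverage (20%),
    expression (1 TPM) and ORF-length (50 aa) cutoffs."""
    fixture = boundary_fixture(seed)
    result = _curate(fixture)
    truth = fixture.truth.set_index("transcript_id")
    calls = result.calls_frame().set_index("transcript_id")
    merged = truth.join(calls, lsuffix="_truth")
    correct = int(
        (
            (merged["category_truth"] == merged["category"])
            & (merged["reason_truth"] == merged["reason"])
        ).sum()
    )
    return {"correct": correct, "n_cases": len(fixture.records)}


def repeat_recovery_sweep(n_replicates: int = 100, base_seed: int = 0) -> dict[str, float]:
    """Segment ``n_replicates`` aciniform-like proteins (ten ~357-aa units,
    5% substitutions, 1% indels) and score unit-count and boundary recovery
    against construction truth."""
    exact = within3 = 0
    fraction_errors: list[float] = []
    for i in range(n_replicates):
        rec, truth = make_spidroin(acsp1_like_spec(seed=base_seed + i))
        part = repeat_arch.partition_domains(
            rec.residues, [NTERM_TEMPLATE], [CTERM_TEMPLATE]
        )
        a, b = part.repeat_region
        units = repeat_arch.segment_repeats(rec.residues[a:b])
        true_bounds = [
            (u.start - truth.partition.a, u.end - truth.partition.a)
            for u in truth.units
        ]
        if len(units) == len(truth.units):
            exact += 1
            errs = [
                max(abs(u.start - ts), abs(u.end - te))
                for u, (ts, te) in zip(units, true_bounds)
            ]
            if max(errs) <= 3:
                within3 += 1
        true_fraction = sum(len(u) for u in truth.units) / len(rec.residues)
        got_fraction = sum(len(u) for u in units) / len(rec.residues)
        fraction_errors.append(abs(got_fraction - true_fraction) * 100)
    return {
        "n_replicates": n_replicates,
        "unit_count_exact_pct": 100.0 * exact / n_replicates,
        "boundary_within3_pct": 100.0 * within3 / n_replicates,
        "repeat_fraction_error_points_max": max(fraction_errors),
    }


def pflag_architecture(seed: int) -> dict[str, float]:
    """Segment and type a pseudoflagelliform-like protein (48 ensemble
    repeats, four module types recurring with period 4, 5% substitutions),
    passing the construction's unit length as the segmentation hint."""
    spec = pflag_like_spec(seed)
    rec, truth = make_spidroin(spec)
    part = repeat_arch.partition_domains(
        rec.residues, [NTERM_TEMPLATE], [CTERM_TEMPLATE]
    )
    a, b = part.repeat_region
    units = repeat_arch.segment_repeats(rec.residues[a:b], unit_hint=spec.unit_len)
    out: dict[str, float] = {"n_units": len(units), "n_true_units": len(truth.units)}
    if len(units) >= 2:
        matrix = repeat_arch.pairwise_identity_matrix(units)
        labels = repeat_arch.cluster_repeat_types(matrix)
        out["n_types"] = len(set(labels))
        period, mismatch = repeat_arch.higher_order_period(labels)
        out["higher_order_period"] = period if period is not None else 0
        out["period_mismatch"] = mismatch
    return out


def _random_additive_case(rng: np.random.Generator, n_taxa: int):
    names = [f"t{i}" for i in range(n_taxa)]
    nodes = [
        phylo.TreeNode(name=n, length=float(np.round(rng.uniform(0.5, 5), 3)))
        for n in names
    ]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = phylo.TreeNode(length=float(np.round(rng.uniform(0.5, 5), 3)))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent.extend([a, b])
        nodes.append(parent)
    root = phylo.TreeNode()
    root.extend(nodes)
    tt = root.tip_tip_distances()
    return list(map(str, tt.ids)), np.asarray(tt.data)


def tree_oracles(seed: int, n_matrices: int = 20) -> dict[str, float]:
    """Neighbor joining on random additive 4/5-taxon matrices (exact
    patristic recovery), the 3-leaf UPGMA worked example, and bootstrap
    support for a planted two-clade alignment."""
    rng = np.random.default_rng(seed)
    exact = 0
    for i in range(n_matrices):
        ids, D = _random_additive_case(rng, 4 if i % 2 == 0 else 5)
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, D))
        rt = tree.tip_tip_distances(endpoints=ids)
        if np.allclose(np.asarray(rt.data), D, atol=1e-9):
            exact += 1
    dm = phylo.DistanceMatrix(
        ["x", "y", "z"], np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
    )
    upgma = phylo.upgma_tree(dm)
    tip_x = upgma.find("x")
    cherry = tip_x.parent
    upgma_height_error = abs(tip_x.length - 0.1) + abs((tip_x.length + cherry.length) - 0.3)
    msa = phylo.Alignment(rows=[
        ("A1", "AAAAAAAAAACCCCCCCCCC"),
        ("A2", "AAAAAAAAAACCCCCCCCCC"),
        ("B1", "GGGGGGGGGGTTTTTTTTTT"),
        ("B2", "GGGGGGGGGGTTTTTTTTTT"),
    ])
    boot = phylo.bootstrap_support(msa, phylo.nj_tree, n_replicates=100, seed=seed)
    supports = [
        n.support for n in boot.non_tips(include_self=False) if getattr(n, "support", None) is not None
    ]
    boot2 = phylo.bootstrap_support(msa, phylo.nj_tree, n_replicates=100, seed=seed)
    supports2 = [
        n.support for n in boot2.non_tips(include_self=False) if getattr(n, "support", None) is not None
    ]
    return {
        "n_matrices": n_matrices,
        "nj_additive_recovery_pct": 100.0 * exact / n_matrices,
        "upgma_height_error": upgma_height_error,
        "two_clade_support_pct": min(supports) if supports else 0.0,
        "bootstrap_deterministic": float(supports == supports2),
    }
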