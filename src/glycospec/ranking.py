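"""Glycan structural-isomer rescoring by predicted-spectrum library search.

A query spectrum is compared against the predicted spectra of candidate
glycopeptides that share the peptide, charge and monosaccharide composition
but differ in glycan topology.  Candidates are scored with
``alpha*(1-SA_Y) + beta*(1-SA_B)`` and ranked; query peaks that match no
candidate's theoretical fragments never enter any aligned intensity vector,
so the stated discard rule is score-neutral by construction.  The attention
weights of the fragmentation graph are exported for explanation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .fragments import FragmentIndex, GlycopeptidePrecursor, build_fragmentation_graph
from .glycans import GlycanTree, detect_core, enumerate_isomers, serialize_canonical
from .metrics import RankingWeights, ranking_score, spectral_angle
from .network import GlycoSpectrumNetwork
from .spectra import Spectrum, match_peaks

__all__ = [
    "CandidateResult",
    "generate_candidates",
    "rank_candidates",
    "summarize_recognition",
    "explain_candidate",
]


@dataclass
class CandidateResult:
    precursor: GlycopeptidePrecursor
    glycan_string: str
    sa_Y: float
    sa_B: float | None
    sa_pep: float | None  # reported, not part of the ranking score
    score: float
    rank: int
    core_fucose: bool
    bisecting: bool


def generate_candidates(
    precursor: GlycopeptidePrecursor, space: Sequence[GlycanTree]
) -> list[GlycopeptidePrecursor]:
    """Candidates replacing the glycan with every isomer in ``space``."""
    comp = precursor.glycan.composition()
    return [
        GlycopeptidePrecursor(precursor.peptide, iso, precursor.charge)
        for iso in enumerate_isomers(comp, space)
    ]


def _part_sa(query_vec: np.ndarray, pred_vec: np.ndarray) -> float | None:
    """SA of one part; None when either side carries no intensity."""
    if query_vec.size == 0 or query_vec.sum() <= 0 or pred_vec.sum() <= 0:
        return None
    return spectral_angle(query_vec, pred_vec)


def rank_candidates(
    query: Spectrum,
    candidates: Sequence[GlycopeptidePrecursor],
    net: GlycoSpectrumNetwork,
    weights: RankingWeights = RankingWeights(),
    tol_ppm: float = 20.0,
) -> list[CandidateResult]:
    """Score and rank candidate glycopeptides against a query peak list.

    Ties are broken by canonical glycan string; a candidate whose Y part
    matches no query peak scores worst (SA_Y = 1).
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    results = []
    any_matched = False
    for cand in candidates:
        index = FragmentIndex(cand, with_B=net.config.with_B)
        pred = net.predict(index)
        ann = match_peaks(query, cand, tol_ppm=tol_ppm, index=index)
        sa_Y = _part_sa(ann.s_y, pred.y)
        if sa_Y is not None:
            any_matched = True
        sa_B = _part_sa(ann.s_b, pred.b)
        sa_pep = _part_sa(ann.s_pep, pred.pep)
        score = ranking_score(1.0 if sa_Y is None else sa_Y, sa_B, weights)
        core = detect_core(cand.glycan)
        results.append(
            CandidateResult(
                precursor=cand,
                glycan_string=serialize_canonical(cand.glycan),
                sa_Y=1.0 if sa_Y is None else sa_Y,
                sa_B=sa_B,
                sa_pep=sa_pep,
                score=score,
                rank=0,
                core_fucose=core.core_fucose,
                bisecting=core.bisecting,
            )
        )
    if not any_matched:
        raise ValueError("query spectrum has no peaks matchable to any candidate")
    results.sort(key=lambda r: (-r.score, r.glycan_string))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def summarize_recognition(
    ranked: Sequence[Sequence[CandidateResult]],
    true_glycans: Sequence[GlycanTree],
) -> dict:
    """Top-k rates and structural-flag confusion matrices over a dataset.

    The rank-k rate counts spectra whose correct identity ranked exactly k-th
    out of the spectra with more than k candidates; ``top3_rate`` counts
    ranks 1-3 out of spectra with more than 3 candidates.  For the
    core-fucose and bisecting confusion matrices, spectra whose candidates
    all share the category are excluded.
    """
    true_strings = [serialize_canonical(t) for t in true_glycans]
    ranks = []
    n_cands = []
    for results, ts in zip(ranked, true_strings):
        rank = next((r.rank for r in results if r.glycan_string == ts), None)
        ranks.append(rank)
        n_cands.append(len(results))
    out: dict = {"n_spectra": len(ranks)}
    for k in (1, 2, 3):
        eligible = [
            (r, n) for r, n in zip(ranks, n_cands) if n > k and r is not None
        ]
        out[f"rank{k}_rate"] = (
            sum(1 for r, _ in eligible if r == k) / len(eligible)
            if eligible
            else float("nan")
        )
        out[f"n_rank{k}"] = len(eligible)
    eligible3 = [
        (r, n) for r, n in zip(ranks, n_cands) if n > 3 and r is not None
    ]
    out["top1_rate"] = out["rank1_rate"]
    out["top3_rate"] = (
        sum(1 for r, _ in eligible3 if r <= 3) / len(eligible3)
        if eligible3
        else float("nan")
    )
    out["n_top3"] = len(eligible3)

    for flag in ("core_fucose", "bisecting"):
        counts = np.zeros((2, 2), dtype=int)  # [true][predicted]
        for results, ts in zip(ranked, true_strings):
            values = {getattr(r, flag) for r in results}
            if len(values) < 2:
                continue  # all candidates share the category
            truth = next(
                (getattr(r, flag) for r in results if r.glycan_string == ts),
                None,
            )
            if truth is None:
                continue
            pred = getattr(results[0], flag)
            counts[int(truth), int(pred)] += 1
        out[f"{flag}_confusion"] = pd.DataFrame(
            counts,
            index=["true_neg", "true_pos"],
            columns=["pred_neg", "pred_pos"],
        )
    return out


def explain_candidate(
    precursor: GlycopeptidePrecursor, net: GlycoSpectrumNetwork
) -> nx.DiGraph:
    """Fragmentation graph annotated with model weights.

    Structure -> composition edges carry the predicted isomer proportion
    (member intensity / composition intensity; uniform with
    ``degenerate=True`` when the composition intensity is zero); cleavage ->
    structure edges carry the aggregation attention weights.
    """
    index = FragmentIndex(precursor, with_B=net.config.with_B)
    pred = net.predict(index)
    g = build_fragmentation_graph(precursor.glycan, with_B=net.config.with_B)
    struct_int = {
        ("Y", k): float(v.sum()) for k, v in pred.structure_y.items()
    }
    struct_int.update(
        {("B", k): float(v.sum()) for k, v in pred.structure_b.items()}
    )
    for ion_class, groups in (("Y", index.y_groups), ("B", index.b_groups)):
        for comp, members in groups:
            ckey = ("composition", ion_class, str(comp))
            total = sum(
                struct_int.get((ion_class, m.retained_ids), 0.0)
                for m in members
            )
            for m in members:
                skey = ("structure", ion_class, m.retained_ids)
                if total > 0:
                    w = struct_int.get((ion_class, m.retained_ids), 0.0) / total
                    g.edges[skey, ckey]["weight"] = w
                else:
                    g.edges[skey, ckey]["weight"] = 1.0 / len(members)
                    g.edges[skey, ckey]["degenerate"] = True
    attn = {"Y": pred.fragment_attention.get("Y", {}),
            "B": pred.fragment_attention.get("B", {})}
    for ion_class, frags in (("Y", index.y_structures), ("B", index.b_structures)):
        for f in frags:
            skey = ("structure", ion_class, f.retained_ids)
            w_by_edge = attn[ion_class].get(f.retained_ids, {})
            for s in f.cleavages:
                ckey = ("cleavage", s.edge)
                if (ckey, skey) in g.edges:
                    g.edges[ckey, skey]["weight"] = float(
                        w_by_edge.get(s.edge, 1.0 / len(f.cleavages))
                    )
    return g
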