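"""Gain and loss calling for phosphorylation sites across accessions.

Two kinds of events are called per (protein, position, accession):

* **status 2** — the central residue itself changes: a phosphorylated (or
  high-confidence predicted) S/T/Y is substituted away (loss), or a
  non-phosphorylatable residue becomes an S/T/Y whose predicted score is in
  the high-confidence positive regime (gain).
* **status 1** — the central S/T/Y is retained but substitutions in its +/-6
  sequence context move the prediction score across the high-confidence
  bands: from >= 1 down to <= -1 (loss) or from <= -1 up to >= 1 (gain).

Scores strictly inside (-1, 1) on either side yield no call.  The score
thresholds are inclusive: exactly 1 and exactly -1 are high confidence.

The scorer is an injected callable ``(sequence, 1-based position) -> float``;
the package ships a deterministic toy scorer (a fixed weighted +/-6 window
motif score squashed into (-3, 3)) so the score-based logic is fully
exercisable without an external predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .core_io import PHOSPHO_RESIDUES, PhosphoSite
from .variant_mapping import ProteinEffect

Scorer = Callable[[str, int], float]

HIGH_POS = 1.0  # score >= HIGH_POS: high-confidence site
HIGH_NEG = -1.0  # score <= HIGH_NEG: high-confidence non-site


class ToyScorer:
    """Deterministic +/-6 window motif scorer mapped into (-3, 3).

    The raw score is a central-residue offset plus a distance-weighted sum of
    fixed neighbour values (basic residues score positive, helix-breaking /
    acidic residues negative), squashed through 3*tanh(raw/1.5).  The
    constants are chosen so that both high-confidence regimes (>= 1 and
    <= -1) are reachable from each other by a single neighbour substitution
    close to the central residue.  Residues missing from the window (protein
    ends) contribute zero.
    """

    CENTRAL = {"S": 0.2, "T": 0.0, "Y": -0.2}
    NEIGHBOR_VALUE = {
        "R": 1.0,
        "K": 0.8,
        "H": 0.4,
        "Q": 0.2,
        "N": 0.2,
        "S": 0.1,
        "T": 0.1,
        "Y": 0.1,
        "P": -1.0,
        "D": -0.8,
        "E": -0.7,
        "G": -0.2,
    }
    WEIGHT_BY_DISTANCE = {1: 0.6, 2: 0.6, 3: 0.3, 4: 0.3, 5: 0.15, 6: 0.15}

    def __call__(self, sequence: str, position: int) -> float:
        if not (1 <= position <= len(sequence)):
            raise ValueError(f"position {position} outside sequence")
        central = sequence[position - 1]
        if central not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"scorer undefined at position {position}: residue {central!r}"
            )
        raw = self.CENTRAL[central]
        for dist, weight in self.WEIGHT_BY_DISTANCE.items():
            for idx in (position - 1 - dist, position - 1 + dist):
                if 0 <= idx < len(sequence):
                    raw += weight * self.NEIGHBOR_VALUE.get(sequence[idx], 0.0)
        return 3.0 * math.tanh(raw / 1.5)


toy_scorer = ToyScorer()


class TableScorer:
    """Scorer backed by precomputed (protein, position, accession, score) rows.

    Reference-sequence scores use an empty accession field.  The calling code
    announces which (protein, accession) pair it is scoring through
    :meth:`set_context`; the scorer then distinguishes reference from
    accession sequences by comparison with the reference proteome.
    """

    def __init__(
        self,
        proteome: dict[str, str],
        table: dict[tuple[str, int, str], float],
    ) -> None:
        self.proteome = proteome
        self.table = table
        self._protein_id: str | None = None
        self._accession: str = ""

    def set_context(self, protein_id: str, accession: str) -> None:
        self._protein_id = protein_id
        self._accession = accession

    def __call__(self, sequence: str, position: int) -> float:
        if self._protein_id is None:
            raise ValueError("TableScorer used without set_context")
        acc = "" if sequence == self.proteome[self._protein_id] else self._accession
        key = (self._protein_id, position, acc)
        if key not in self.table:
            raise ValueError(
                f"scorer undefined at required position {key!r}"
            )
        return self.table[key]


@dataclass(frozen=True)
class GainLossEvent:
    """One called gain or loss of a phosphosite in one accession."""

    protein_id: str
    position: int
    accession: str
    kind: str  # loss | gain
    status: int  # 1 = score-based, 2 = substitution-based
    ref_residue: str
    alt_residue: str
    ref_score: float | None = None
    alt_score: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("loss", "gain"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.status not in (1, 2):
            raise ValueError(f"bad status {self.status}")
        if self.status == 1 and self.ref_residue != self.alt_residue:
            raise ValueError("status-1 events never change the central residue")
        if self.status == 2 and self.ref_residue == self.alt_residue:
            raise ValueError("status-2 events always change the central residue")


# ---------------------------------------------------------------------------
# Experimental losses
# ---------------------------------------------------------------------------


def call_experimental_losses(
    sites: Sequence[PhosphoSite],
    effects: Sequence[ProteinEffect],
    strict: bool = False,
) -> list[GainLossEvent]:
    """Losses of experimental phosphosites by amino-acid exchange.

    A loss is recorded for every accession whose nonsynonymous substitution
    changes the phosphorylated residue into any other amino acid; the default
    therefore includes exchanges to another phosphorylatable residue
    (e.g. S -> T).  ``strict=True`` restricts to non-phosphorylatable
    targets only.
    """
    by_pos: dict[tuple[str, int], list[ProteinEffect]] = {}
    for eff in effects:
        by_pos.setdefault((eff.protein_id, eff.protein_pos), []).append(eff)
    events = []
    for site in sites:
        if site.status != "experimental":
            continue
        for eff in by_pos.get((site.protein_id, site.position), ()):
            if eff.effect_class == "synonymous":
                continue
            if eff.ref_aa != site.residue:
                raise ValueError(
                    f"site/effect mismatch at {site.protein_id}:{site.position}: "
                    f"site residue {site.residue}, effect ref {eff.ref_aa}"
                )
            if strict and eff.alt_aa in PHOSPHO_RESIDUES:
                continue
            for accession in sorted(eff.accessions):
                events.append(
                    GainLossEvent(
                        protein_id=site.protein_id,
                        position=site.position,
                        accession=accession,
                        kind="loss",
                        status=2,
                        ref_residue=site.residue,
                        alt_residue=eff.alt_aa,
                    )
                )
    return events


# ---------------------------------------------------------------------------
# Predicted gains and losses
# ---------------------------------------------------------------------------


def apply_accession_effects(
    ref_seq: str, effects: Sequence[ProteinEffect]
) -> str:
    """Protein sequence of one accession: apply all its substitutions.

    Stop-codon effects beyond the protein body are ignored; a premature stop
    is written as '*' (context scoring past it is a documented
    simplification).
    """
    seq = list(ref_seq)
    for eff in effects:
        if eff.protein_pos > len(seq):
            continue
        if eff.effect_class == "synonymous":
            continue
        seq[eff.protein_pos - 1] = eff.alt_aa
    return "".join(seq)


def call_predicted_gain_loss(
    sites: Sequence[PhosphoSite],
    effects: Sequence[ProteinEffect],
    scorer: Scorer,
    proteome: dict[str, str],
) -> tuple[list[GainLossEvent], dict[str, int]]:
    """Gains and losses of predicted phosphosites, per accession.

    Returns the called events plus a counter of indeterminate outcomes
    (post-substitution scores strictly inside the (-1, 1) band, and
    STY -> STY central exchanges, which fit neither status definition).
    """
    pred_sites = [s for s in sites if s.status == "predicted"]
    for site in pred_sites:
        if site.score is None or site.score < HIGH_POS:
            raise ValueError(
                f"predicted site {site.protein_id}:{site.position} has "
                f"score {site.score}; the input set must be high-confidence (>= 1)"
            )
    sites_by_protein: dict[str, dict[int, PhosphoSite]] = {}
    for site in pred_sites:
        sites_by_protein.setdefault(site.protein_id, {})[site.position] = site

    by_pa: dict[tuple[str, str], list[ProteinEffect]] = {}
    for eff in effects:
        for accession in eff.accessions:
            by_pa.setdefault((eff.protein_id, accession), []).append(eff)

    events: list[GainLossEvent] = []
    no_call = {"score_indeterminate": 0, "sty_to_sty": 0}
    for (pid, accession), eff_list in sorted(by_pa.items()):
        if hasattr(scorer, "set_context"):
            scorer.set_context(pid, accession)
        ref_seq = proteome[pid]
        nonsyn = [
            e
            for e in eff_list
            if e.effect_class != "synonymous" and e.protein_pos <= len(ref_seq)
        ]
        if not nonsyn:
            continue
        mut_seq = apply_accession_effects(ref_seq, nonsyn)
        changed_pos = {e.protein_pos for e in nonsyn}
        site_map = sites_by_protein.get(pid, {})

        # status 2: the central residue itself is exchanged
        for eff in nonsyn:
            pos = eff.protein_pos
            if pos in site_map:
                if eff.alt_aa in PHOSPHO_RESIDUES:
                    no_call["sty_to_sty"] += 1
                    continue
                events.append(
                    GainLossEvent(
                        pid, pos, accession, "loss", 2,
                        ref_residue=eff.ref_aa, alt_residue=eff.alt_aa,
                        ref_score=site_map[pos].score,
                    )
                )
            elif (
                eff.ref_aa not in PHOSPHO_RESIDUES
                and eff.ref_aa != "*"
                and eff.alt_aa in PHOSPHO_RESIDUES
            ):
                alt_score = scorer(mut_seq, pos)
                if alt_score >= HIGH_POS:
                    events.append(
                        GainLossEvent(
                            pid, pos, accession, "gain", 2,
                            ref_residue=eff.ref_aa, alt_residue=eff.alt_aa,
                            alt_score=alt_score,
                        )
                    )
                else:
                    no_call["score_indeterminate"] += 1

        # status 1: central retained, context changed within +/-6
        candidates: set[int] = set()
        for pos in changed_pos:
            lo, hi = max(1, pos - 6), min(len(ref_seq), pos + 6)
            for p in range(lo, hi + 1):
                if p not in changed_pos and ref_seq[p - 1] in PHOSPHO_RESIDUES:
                    candidates.add(p)
        for pos in sorted(candidates):
            residue = ref_seq[pos - 1]
            if pos in site_map:
                ref_score = site_map[pos].score
            else:
                ref_score = scorer(ref_seq, pos)
            alt_score = scorer(mut_seq, pos)
            if ref_score >= HIGH_POS and alt_score <= HIGH_NEG:
                events.append(
                    GainLossEvent(
                        pid, pos, accession, "loss", 1,
                        ref_residue=residue, alt_residue=residue,
                        ref_score=ref_score, alt_score=alt_score,
                    )
                )
            elif ref_score <= HIGH_NEG and alt_score >= HIGH_POS:
                events.append(
                    GainLossEvent(
                        pid, pos, accession, "gain", 1,
                        ref_residue=residue, alt_residue=residue,
                        ref_score=ref_score, alt_score=alt_score,
                    )
                )
            elif (ref_score >= HIGH_POS or ref_score <= HIGH_NEG) and (
                HIGH_NEG < alt_score < HIGH_POS
            ):
                no_call["score_indeterminate"] += 1
    return events, no_call


def summarize_gain_loss(events: Sequence[GainLossEvent]) -> dict:
    """Distinct-protein counts per kind and per-status event tallies."""
    proteins: dict[str, set[str]] = {"loss": set(), "gain": set()}
    by_status: dict[tuple[str, int], int] = {}
    for ev in events:
        proteins[ev.kind].add(ev.protein_id)
        by_status[(ev.kind, ev.status)] = by_status.get((ev.kind, ev.status), 0) + 1
    return {
        "n_loss_proteins": len(proteins["loss"]),
        "n_gain_proteins": len(proteins["gain"]),
        "n_loss_status1": by_status.get(("loss", 1), 0),
        "n_loss_status2": by_status.get(("loss", 2), 0),
        "n_gain_status1": by_status.get(("gain", 1), 0),
        "n_gain_status2": by_status.get(("gain", 2), 0),
    }


def events_to_frame(events: Sequence[GainLossEvent]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": e.protein_id,
            "position": e.position,
            "accession": e.accession,
            "kind": e.kind,
            "status": e.status,
            "ref_residue": e.ref_residue,
            "alt_residue": e.alt_residue,
            "ref_score": "" if e.ref_score is None else round(e.ref_score, 4),
            "alt_score": "" if e.alt_score is None else round(e.alt_score, 4),
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "position", "accession", "kind", "status",
            "ref_residue", "alt_residue", "ref_score", "alt_score",
        ],
    )
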