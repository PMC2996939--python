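"""Sliding-window phosphorylation hotspot detection against simulated
background proteomes, run merging, and the hotspot-domain overlap test.

A hotspot is a fixed-length window whose phosphosite count (experimental
mode) or prediction-score sum (predicted mode) is improbably high under an
empirical background distribution.  The background pools deduplicated window
scores from many replicate proteomes sampled to match the real proteome's
length multiset, residue composition and per-residue phosphorylation
probabilities (or prediction-score distribution).  Window p-values are
right-tail empirical probabilities with the add-one estimator and are
Bonferroni-corrected by the number of candidate windows tested.

Windows step by one residue; consecutive windows containing the identical
set of S/T/Y residues are counted only once (the first is kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import PHOSPHO_RESIDUES, DomainAnnotation, PhosphoSite

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_STY_CODES = np.array([AA_ORDER.index(r) for r in PHOSPHO_RESIDUES])


@dataclass
class HotspotConfig:
    """Scan settings.

    ``n_background_proteomes`` defaults to 10,000 in experimental mode and
    1,000 in predicted mode when left unset.
    """

    winsize: int = 10
    alpha: float = 5e-2
    mode: str = "experimental"
    n_background_proteomes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.winsize < 1:
            raise ValueError("winsize must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.mode not in ("experimental", "predicted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_background_proteomes is None:
            self.n_background_proteomes = (
                10_000 if self.mode == "experimental" else 1_000
            )


@dataclass(frozen=True)
class HotspotWindow:
    protein_id: str
    start: int  # 1-based first residue of the window
    winsize: int
    score: float
    raw_p: float
    corrected_p: float


@dataclass(frozen=True)
class HotspotRun:
    """Maximal merge of overlapping/adjacent significant windows."""

    protein_id: str
    start: int
    end: int
    windows: tuple[HotspotWindow, ...]


@dataclass
class ProteomeProfile:
    """Statistical fingerprint of a proteome used to build backgrounds."""

    lengths: np.ndarray  # empirical length multiset
    composition: np.ndarray  # probabilities over AA_ORDER
    phospho_prob: dict[str, float] = field(default_factory=dict)  # per S/T/Y
    score_pool: np.ndarray | None = None  # empirical prediction scores
    n_proteins: int = 0

    @property
    def sty_frequency(self) -> float:
        return float(self.composition[_STY_CODES].sum())


def extract_profile(
    proteome: dict[str, str],
    sites: Sequence[PhosphoSite] | None = None,
    scores: dict[str, dict[int, float]] | None = None,
) -> ProteomeProfile:
    """Length multiset, residue composition and phospho rates of a proteome."""
    lengths = np.array([len(seq.rstrip("*")) for seq in proteome.values()])
    counts = np.zeros(len(AA_ORDER))
    for seq in proteome.values():
        for aa in seq.rstrip("*"):
            counts[AA_ORDER.index(aa)] += 1
    if counts[_STY_CODES].sum() == 0:
        raise ValueError("proteome has no S/T/Y residues")
    profile = ProteomeProfile(
        lengths=lengths,
        composition=counts / counts.sum(),
        n_proteins=len(proteome),
    )
    if sites is not None:
        n_sites = {r: 0 for r in PHOSPHO_RESIDUES}
        for site in sites:
            n_sites[site.residue] += 1
        for r in PHOSPHO_RESIDUES:
            n_res = counts[AA_ORDER.index(r)]
            profile.phospho_prob[r] = n_sites[r] / n_res if n_res else 0.0
    if scores is not None:
        pool = [v for per_prot in scores.values() for v in per_prot.values()]
        profile.score_pool = np.asarray(pool, dtype=float)
    return profile


# ---------------------------------------------------------------------------
# Window scanning
# ---------------------------------------------------------------------------


def _dedup_window_scores(
    values: np.ndarray, is_sty: np.ndarray, winsize: int
) -> tuple[np.ndarray, np.ndarray]:
    """Step-1 window sums with duplicate-STY-set windows dropped.

    A window is identical to its predecessor (same S/T/Y residue set) iff
    neither the residue leaving on the left nor the one entering on the
    right is S/T/Y; only the first window of such a stretch is kept.
    Returns (0-based starts, scores).
    """
    n = len(values)
    if n < winsize:
        return np.empty(0, dtype=int), np.empty(0)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    scores = cs[winsize:] - cs[:-winsize]
    keep = np.ones(n - winsize + 1, dtype=bool)
    if n - winsize >= 1:
        keep[1:] = is_sty[: n - winsize] | is_sty[winsize:]
    starts = np.nonzero(keep)[0]
    return starts, scores[keep]


def scan_windows(
    sequence: str,
    values_by_pos: dict[int, float] | Sequence[int],
    winsize: int,
    mode: str = "experimental",
) -> list[tuple[int, float]]:
    """Deduplicated window scores for one protein.

    ``values_by_pos`` is either a collection of phosphosite positions
    (experimental mode, score = count) or a {position: score} map
    (predicted mode, score = sum).  Returns (1-based start, score) pairs.
    A protein shorter than the window yields an empty result with a warning.
    """
    sequence = sequence.rstrip("*")
    n = len(sequence)
    if n < winsize:
        logger.warning("protein shorter than window (%d < %d)", n, winsize)
        return []
    values = np.zeros(n)
    if mode == "experimental":
        for pos in values_by_pos:
            values[pos - 1] = 1.0
    else:
        for pos, score in dict(values_by_pos).items():
            values[pos - 1] = score
    is_sty = np.isin(np.frombuffer(sequence.encode(), dtype=np.uint8),
                     np.frombuffer(b"STY", dtype=np.uint8))
    starts, scores = _dedup_window_scores(values, is_sty, winsize)
    return [(int(s) + 1, float(v)) for s, v in zip(starts, scores)]


# ---------------------------------------------------------------------------
# Background simulation
# ---------------------------------------------------------------------------


@dataclass
class BackgroundDistribution:
    """Pooled deduplicated window scores from replicate null proteomes."""

    mode: str
    winsize: int
    n_windows: int
    # experimental: integer-score histogram; predicted: sorted float scores
    hist: np.ndarray | None = None
    sorted_scores: np.ndarray | None = None

    def count_ge(self, score: float) -> int:
        """Number of background windows scoring >= ``score``."""
        if self.mode == "experimental":
            k = int(np.ceil(score))
            if k >= len(self.hist):
                return 0
            return int(self.hist[max(k, 0):].sum())
        idx = np.searchsorted(self.sorted_scores, score, side="left")
        return int(len(self.sorted_scores) - idx)

    @property
    def mean_score(self) -> float:
        if self.mode == "experimental":
            ks = np.arange(len(self.hist))
            return float((ks * self.hist).sum() / self.hist.sum())
        return float(self.sorted_scores.mean())


def simulate_background(
    profile: ProteomeProfile, config: HotspotConfig
) -> BackgroundDistribution:
    """Empirical window-score distribution over replicate null proteomes.

    Each replicate proteome has the same number of proteins as the real one,
    with lengths resampled with replacement from the real length multiset and
    residues drawn i.i.d. from the global composition.  In experimental mode
    every S/T/Y is phosphorylated independently with its residue-specific
    probability; in predicted mode each S/T/Y receives a score sampled from
    the empirical score pool.  Deterministic for a fixed config seed.
    """
    if profile.sty_frequency == 0:
        raise ValueError("profile has zero S/T/Y frequency")
    if config.mode == "predicted" and (
        profile.score_pool is None or len(profile.score_pool) == 0
    ):
        raise ValueError("predicted mode requires a score pool in the profile")
    rng = np.random.default_rng(config.seed)
    w = config.winsize
    n_total_proteins = config.n_background_proteomes * profile.n_proteins
    # only the S/T/Y identity of a residue matters for window scores, so
    # sample the 4-category marginal (S, T, Y, other) instead of all 20
    sty_comp = np.array(
        [profile.composition[AA_ORDER.index(r)] for r in PHOSPHO_RESIDUES]
    )
    cat_bounds = np.cumsum(sty_comp)  # draws beyond the last bound are "other"
    p_by_cat = np.array(
        [profile.phospho_prob.get(r, 0.0) for r in PHOSPHO_RESIDUES] + [0.0]
    )

    hist = np.zeros(1, dtype=np.int64)
    score_chunks: list[np.ndarray] = []
    n_windows = 0
    mean_len = float(profile.lengths.mean())
    chunk_proteins = max(1, int(5e6 / max(mean_len, 1)))
    done = 0
    while done < n_total_proteins:
        n_prot = min(chunk_proteins, n_total_proteins - done)
        done += n_prot
        lengths = rng.choice(profile.lengths, size=n_prot, replace=True)
        total = int(lengths.sum())
        if total < w:
            continue
        u = rng.random(total, dtype=np.float32)
        is_sty = u < cat_bounds[-1]
        sty_idx = np.flatnonzero(is_sty)
        if config.mode == "experimental":
            u_sty = u[sty_idx].astype(np.float64)
            p_sty = np.where(
                u_sty < cat_bounds[0],
                p_by_cat[0],
                np.where(u_sty < cat_bounds[1], p_by_cat[1], p_by_cat[2]),
            )
            values = np.zeros(total, dtype=np.int8)
            values[sty_idx] = rng.random(len(sty_idx)) < p_sty
            cs = np.concatenate([[0], np.cumsum(values, dtype=np.int64)])
        else:
            values = np.zeros(total)
            values[sty_idx] = rng.choice(
                profile.score_pool, size=len(sty_idx), replace=True
            )
            cs = np.concatenate([[0.0], np.cumsum(values)])
        # window sums over the concatenated array, restricted to windows that
        # do not straddle protein boundaries
        sums = cs[w:] - cs[:-w]
        n_win = total - w + 1
        keep = np.ones(n_win, dtype=bool)
        keep[1:] = is_sty[: total - w] | is_sty[w:]
        ends = np.cumsum(lengths)
        first = np.concatenate([[0], ends[:-1]])
        keep[first[first < n_win]] = True  # first window of each protein
        mask = keep
        valid = np.ones(n_win, dtype=bool)
        for e in ends[:-1]:  # windows straddling a protein boundary
            valid[max(e - w + 1, 0) : min(e, n_win)] = False
        mask &= valid
        chunk_scores = sums[mask]
        n_windows += int(mask.sum())
        if config.mode == "experimental":
            counts = np.bincount(chunk_scores.astype(np.int64))
            if len(counts) > len(hist):
                hist = np.pad(hist, (0, len(counts) - len(hist)))
            hist[: len(counts)] += counts
        else:
            score_chunks.append(chunk_scores)
    if config.mode == "experimental":
        return BackgroundDistribution(
            mode=config.mode, winsize=w, n_windows=n_windows, hist=hist
        )
    pooled = np.sort(np.concatenate(score_chunks)) if score_chunks else np.empty(0)
    return BackgroundDistribution(
        mode=config.mode, winsize=w, n_windows=len(pooled), sorted_scores=pooled
    )


# ---------------------------------------------------------------------------
# Detection, run merging, domain overlap
# ---------------------------------------------------------------------------


def detect_hotspots(
    proteome: dict[str, str],
    sites_or_scores,
    config: HotspotConfig,
    background: BackgroundDistribution | None = None,
    profile: ProteomeProfile | None = None,
) -> list[HotspotWindow]:
    """Significant hotspot windows across a proteome.

    ``sites_or_scores`` is a sequence of PhosphoSite (experimental mode) or a
    {protein_id: {position: score}} map (predicted mode).  The background is
    simulated from the proteome profile unless one is supplied.  Raw
    p-values use the add-one right-tail estimator
    (count_ge(score) + 1) / (n_background_windows + 1); the Bonferroni
    multiplier is the number of candidate windows tested proteome-wide.  In
    predicted mode, candidate windows must contain at least
    floor(winsize * STY frequency) S/T/Y residues (the background is not
    subject to this filter).
    """
    if config.mode == "experimental":
        positions_by_protein: dict[str, list[int]] = {pid: [] for pid in proteome}
        for site in sites_or_scores:
            positions_by_protein.setdefault(site.protein_id, []).append(site.position)
        value_map = positions_by_protein
        if profile is None:
            profile = extract_profile(proteome, sites=list(sites_or_scores))
    else:
        value_map = {pid: sites_or_scores.get(pid, {}) for pid in proteome}
        if profile is None:
            profile = extract_profile(proteome, scores=sites_or_scores)
    if background is None:
        background = simulate_background(profile, config)
    if background.winsize != config.winsize or background.mode != config.mode:
        raise ValueError("background simulated with a different configuration")

    min_sty = int(np.floor(config.winsize * profile.sty_frequency))
    candidates: list[tuple[str, int, float]] = []
    for pid in sorted(proteome):
        seq = proteome[pid].rstrip("*")
        windows = scan_windows(seq, value_map[pid], config.winsize, config.mode)
        if config.mode == "predicted" and windows:
            is_sty = np.isin(
                np.frombuffer(seq.encode(), dtype=np.uint8),
                np.frombuffer(b"STY", dtype=np.uint8),
            ).astype(float)
            for start, score in windows:
                n_sty_in = int(is_sty[start - 1 : start - 1 + config.winsize].sum())
                if n_sty_in >= min_sty:
                    candidates.append((pid, start, score))
        else:
            candidates.extend((pid, start, score) for start, score in windows)

    m = len(candidates)
    out = []
    denom = background.n_windows + 1
    for pid, start, score in candidates:
        raw_p = (background.count_ge(score) + 1) / denom
        corrected = min(1.0, raw_p * m)
        if corrected < config.alpha:
            out.append(
                HotspotWindow(pid, start, config.winsize, score, raw_p, corrected)
            )
    return out


def merge_runs(windows: Sequence[HotspotWindow]) -> list[HotspotRun]:
    """Merge overlapping or bookended significant windows into runs."""
    by_protein: dict[str, list[HotspotWindow]] = {}
    for win in windows:
        by_protein.setdefault(win.protein_id, []).append(win)
    runs = []
    for pid in sorted(by_protein):
        wins = sorted(by_protein[pid], key=lambda w: w.start)
        cur = [wins[0]]
        cur_end = wins[0].start + wins[0].winsize - 1
        for win in wins[1:]:
            if win.start <= cur_end + 1:  # overlapping or adjacent
                cur.append(win)
                cur_end = max(cur_end, win.start + win.winsize - 1)
            else:
                runs.append(HotspotRun(pid, cur[0].start, cur_end, tuple(cur)))
                cur = [win]
                cur_end = win.start + win.winsize - 1
        runs.append(HotspotRun(pid, cur[0].start, cur_end, tuple(cur)))
    return runs


def domain_overlap_test(
    hotspots: Sequence[HotspotRun] | Sequence[HotspotWindow],
    domains: Sequence[DomainAnnotation],
    proteome: dict[str, str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation test of hotspot placement relative to protein domains.

    The observed statistic is the number of hotspot intervals intersecting
    any domain of their protein.  The null redraws each hotspot's start
    uniformly within its own protein (same length), ``n_permutations``
    times.  P-values use the add-one estimator; depletion asks whether
    hotspots avoid domains, enrichment whether they seek them.
    """
    rng = np.random.default_rng(seed)
    doms_by_protein: dict[str, list[tuple[int, int]]] = {}
    for dom in domains:
        doms_by_protein.setdefault(dom.protein_id, []).append((dom.start, dom.end))

    intervals = []
    for hs in hotspots:
        if isinstance(hs, HotspotWindow):
            intervals.append((hs.protein_id, hs.start, hs.start + hs.winsize - 1))
        else:
            intervals.append((hs.protein_id, hs.start, hs.end))

    observed = 0
    overlap_prob_masks = []  # per hotspot: boolean over possible starts
    for pid, start, end in intervals:
        length = end - start + 1
        protein_len = len(proteome[pid].rstrip("*"))
        if protein_len < length:
            logger.warning("hotspot longer than protein %s; placement skipped", pid)
            continue
        doms = doms_by_protein.get(pid, [])
        if any(start <= d_end and end >= d_start for d_start, d_end in doms):
            observed += 1
        n_starts = protein_len - length + 1
        mask = np.zeros(n_starts, dtype=bool)
        for d_start, d_end in doms:
            lo = max(1, d_start - length + 1)
            hi = min(n_starts, d_end)
            if lo <= hi:
                mask[lo - 1 : hi] = True
        overlap_prob_masks.append(mask)

    if not overlap_prob_masks or not domains:
        return {
            "observed_overlap": observed,
            "p_depletion": 1.0,
            "p_enrichment": 1.0,
            "n_permutations": n_permutations,
        }
    counts = np.zeros(n_permutations, dtype=np.int64)
    for mask in overlap_prob_masks:
        draws = rng.integers(0, len(mask), size=n_permutations)
        counts += mask[draws]
    p_depletion = (int((counts <= observed).sum()) + 1) / (n_permutations + 1)
    p_enrichment = (int((counts >= observed).sum()) + 1) / (n_permutations + 1)
    return {
        "observed_overlap": observed,
        "p_depletion": float(p_depletion),
        "p_enrichment": float(p_enrichment),
        "n_permutations": n_permutations,
    }


def windows_to_frame(windows: Sequence[HotspotWindow]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": w.protein_id,
            "start": w.start,
            "winsize": w.winsize,
            "score": w.score,
            "raw_p": w.raw_p,
            "corrected_p": w.corrected_p,
        }
        for w in windows
    ]
    return pd.DataFrame(
        rows, columns=["protein_id", "start", "winsize", "score", "raw_p",
                       "corrected_p"]
    )


def windows_summary_frame(windows: Sequence[HotspotWindow]) -> pd.DataFrame:
    """Per-protein summary with 'score(start)' descriptors."""
    by_protein: dict[str, list[HotspotWindow]] = {}
    for win in windows:
        by_protein.setdefault(win.protein_id, []).append(win)
    rows = []
    for pid in sorted(by_protein):
        wins = by_protein[pid]
        desc = ", ".join(f"{w.score:g}({w.start})" for w in wins)
        rows.append(
            {
                "protein_id": pid,
                "n_significant_windows": len(wins),
                "windows": desc,
            }
        )
    return pd.DataFrame(
        rows, columns=["protein_id", "n_significant_windows", "windows"]
    )


def runs_to_frame(runs: Sequence[HotspotRun]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": r.protein_id,
            "start": r.start,
            "end": r.end,
            "n_windows": len(r.windows),
        }
        for r in runs
    ]
    return pd.DataFrame(rows, columns=["protein_id", "start", "end", "n_windows"])
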