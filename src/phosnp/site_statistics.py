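"""Residue-type proportions, the phosphosite-count null model, and
phospho- vs non-phospho substitution enrichment.

The count null model assumes every S/T/Y residue is phosphorylated with one
global probability p = (total phosphosites) / (total S+T+Y residues),
independent of how many phosphorylatable residues a protein has.  The
expected number of sites for protein x is then E_x = p * n_STY(x), and the
expected frequency-of-count histogram follows from the per-protein binomial
law Binom(n_STY(x), p) summed over proteins.  Departures from this null
(excess singletons, a heavy right tail) are the diagnostic of interest.

Substitution enrichment contrasts, for each substitution pair from S/T/Y to
any of the 20 amino acids or stop, how often phosphorylated versus
non-phosphorylated residues of that type carry the substitution, with a 2x2
Fisher's exact test per pair and Benjamini-Hochberg FDR across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .codon_effects import substitution_cost
from .core_io import PHOSPHO_RESIDUES, DomainAnnotation, PhosphoSite

if TYPE_CHECKING:  # pragma: no cover
    from .variant_mapping import ProteinEffect


# ---------------------------------------------------------------------------
# Residue proportions and domain location
# ---------------------------------------------------------------------------


@dataclass
class ResidueProportions:
    """Counts of pS/pT/pY with full-precision and 1-decimal percentages."""

    counts: dict[str, int]
    percent: dict[str, float]
    display: dict[str, float]


def residue_proportions(sites: Sequence[PhosphoSite]) -> ResidueProportions:
    """Percentage of phosphosites on S, T and Y."""
    if not sites:
        raise ValueError("empty site set")
    counts = {r: 0 for r in PHOSPHO_RESIDUES}
    for site in sites:
        counts[site.residue] += 1
    return proportions_from_counts(counts)


def proportions_from_counts(counts: dict[str, int]) -> ResidueProportions:
    """Residue proportions from raw per-residue counts."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty site set")
    percent = {r: 100.0 * counts.get(r, 0) / total for r in PHOSPHO_RESIDUES}
    display = {r: round(v, 1) for r, v in percent.items()}
    return ResidueProportions(dict(counts), percent, display)


def domain_location_fraction(
    sites: Sequence[PhosphoSite], domains: Sequence[DomainAnnotation]
) -> pd.DataFrame:
    """Fraction of phosphosites falling inside annotated domains, per residue.

    A site is "inside" iff some domain of its protein satisfies
    start <= position <= end (inclusive on both ends).
    """
    by_protein: dict[str, list[tuple[int, int]]] = {}
    for dom in domains:
        by_protein.setdefault(dom.protein_id, []).append((dom.start, dom.end))
    rows = {r: {"residue": r, "n_inside": 0, "n_total": 0} for r in PHOSPHO_RESIDUES}
    for site in sites:
        rows[site.residue]["n_total"] += 1
        inside = any(
            start <= site.position <= end
            for start, end in by_protein.get(site.protein_id, ())
        )
        if inside:
            rows[site.residue]["n_inside"] += 1
    df = pd.DataFrame(list(rows.values()))
    df["fraction_inside"] = df["n_inside"] / df["n_total"].where(df["n_total"] > 0)
    return df


# ---------------------------------------------------------------------------
# Phosphosite-count null model
# ---------------------------------------------------------------------------


@dataclass
class DistributionNull:
    """Constant-probability null for the sites-per-protein distribution.

    ``expected_count`` maps protein id -> E_x = p * n_STY(x).  The histograms
    index frequency of proteins by site count k; ``expected_hist[k]`` sums
    Binom(n_STY(x), p).pmf(k) over proteins.  Conservation holds exactly:
    sum of E_x equals the observed total site count (p is kept as an exact
    fraction for that check).
    """

    p: float
    p_exact: Fraction
    total_sites: int
    total_sty: int
    expected_count: dict[str, float]
    observed_hist: np.ndarray
    expected_hist: np.ndarray

    @property
    def expected_total_exact(self) -> Fraction:
        return self.p_exact * self.total_sty

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": np.arange(len(self.observed_hist)),
                "observed": self.observed_hist,
                "expected": self.expected_hist,
            }
        )


def count_sty(sequence: str) -> int:
    return sum(sequence.count(r) for r in PHOSPHO_RESIDUES)


def expected_count_distribution(
    proteome: dict[str, str], sites: Sequence[PhosphoSite]
) -> DistributionNull:
    """Fit the constant-probability null to a proteome and its site set."""
    n_sty = {pid: count_sty(seq) for pid, seq in proteome.items()}
    total_sty = sum(n_sty.values())
    if total_sty == 0:
        raise ValueError("proteome contains no S/T/Y residues")
    observed: dict[str, int] = {pid: 0 for pid in proteome}
    for site in sites:
        if site.protein_id not in observed:
            raise ValueError(f"site on unknown protein {site.protein_id}")
        observed[site.protein_id] += 1
    total_sites = sum(observed.values())
    p_exact = Fraction(total_sites, total_sty)
    p = float(p_exact)
    kmax = max(max(observed.values(), default=0), 0)
    obs_hist = np.bincount(list(observed.values()), minlength=kmax + 1)
    ns = np.array([n_sty[pid] for pid in proteome])
    ks = np.arange(kmax + 1)
    # binomial pmf per protein, summed: matrix (proteins x counts)
    pmf = sps.binom.pmf(ks[None, :], ns[:, None], p)
    exp_hist = pmf.sum(axis=0)
    expected_count = {pid: p * n_sty[pid] for pid in proteome}
    return DistributionNull(
        p=p,
        p_exact=p_exact,
        total_sites=total_sites,
        total_sty=total_sty,
        expected_count=expected_count,
        observed_hist=obs_hist,
        expected_hist=exp_hist,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test and BH-FDR
# ---------------------------------------------------------------------------


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table of counts.

    The two-sided p-value sums all hypergeometric outcomes whose probability
    does not exceed that of the observed table.  The odds ratio is the
    sample estimate a*d / (b*c), with a Haldane-Anscombe 0.5 correction when
    any cell is zero.  A zero margin yields p = 1 and an undefined (NaN)
    odds ratio.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(x != int(x) for x in (a, b, c, d)):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    if 0 in (r1, r2, c1, b + d):
        return 1.0, float("nan")
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    kmin, kmax = max(0, c1 - r2), min(c1, r1)
    ks = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(p, 1.0), float(odds)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p_values = list(p_values)
    if not p_values:
        return []
    if any(p < 0 or p > 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(v) for v in q]


# ---------------------------------------------------------------------------
# Substitution enrichment at phosphosites (Fisher 2x2 per pair)
# ---------------------------------------------------------------------------

TO_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY*"


def substitution_enrichment(
    sites: Sequence[PhosphoSite],
    effects: Sequence["ProteinEffect"],
    proteome: dict[str, str],
    universe: str = "snp_on_site",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of each substitution pair at phospho- vs non-phospho-sites.

    For each from-residue in {S, T, Y} and each target (20 amino acids plus
    stop, including the synonymous self-pair), positions of the from-residue
    in the universe are split into phosphorylated and non-phosphorylated, and
    a position counts as substituted when at least one accession carries the
    substitution to the target.  The 2x2 layout is rows = phospho /
    non-phospho, columns = substituted / not, so an odds ratio > 1 reads
    "enriched at phosphosites".  BH-FDR is applied across all tested pairs;
    pairs observed in neither class are reported as never observed and not
    tested.

    ``universe`` selects the protein background: ``snp_on_site`` keeps
    proteins with at least one SNP effect mapping onto a phosphosite
    position; ``phosphoproteins`` keeps every protein carrying a site.
    """
    site_positions: dict[str, set[int]] = {}
    for site in sites:
        site_positions.setdefault(site.protein_id, set()).add(site.position)
    if universe == "phosphoproteins":
        universe_ids = set(site_positions)
    elif universe == "snp_on_site":
        universe_ids = {
            e.protein_id
            for e in effects
            if e.protein_pos in site_positions.get(e.protein_id, ())
        }
    else:
        raise ValueError(f"unknown universe {universe!r}")
    if not universe_ids:
        raise ValueError("empty universe: no proteins satisfy the universe rule")

    # substitution targets observed per (protein, position)
    subs_at: dict[tuple[str, int], set[str]] = {}
    for eff in effects:
        if eff.protein_id not in universe_ids or eff.ref_aa == "*":
            continue
        target = eff.ref_aa if eff.effect_class == "synonymous" else eff.alt_aa
        subs_at.setdefault((eff.protein_id, eff.protein_pos), set()).add(target)

    rows = []
    for from_res in PHOSPHO_RESIDUES:
        phospho: list[tuple[str, int]] = []
        nonphospho: list[tuple[str, int]] = []
        for pid in universe_ids:
            seq = proteome[pid]
            marked = site_positions.get(pid, set())
            for pos0, aa in enumerate(seq):
                if aa != from_res:
                    continue
                pos = pos0 + 1
                (phospho if pos in marked else nonphospho).append((pid, pos))
        n_ph, n_nonph = len(phospho), len(nonphospho)
        for to_sym in TO_SYMBOLS:
            a = sum(1 for key in phospho if to_sym in subs_at.get(key, ()))
            c = sum(1 for key in nonphospho if to_sym in subs_at.get(key, ()))
            never = (a + c) == 0
            if never:
                p_val, odds = float("nan"), float("nan")
            else:
                p_val, odds = fisher_exact([[a, n_ph - a], [c, n_nonph - c]])
            rows.append(
                {
                    "from_residue": from_res,
                    "to_symbol": to_sym,
                    "cost": substitution_cost(from_res, to_sym),
                    "n_phospho": n_ph,
                    "n_nonphospho": n_nonph,
                    "phospho_hit": a,
                    "nonphospho_hit": c,
                    "odds_ratio": odds,
                    "p_value": p_val,
                    "never_observed": never,
                }
            )
    df = pd.DataFrame(rows)
    tested = ~df["never_observed"]
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(df.loc[tested, "p_value"].to_list())
    df["q_value"] = q
    df["significant"] = df["q_value"] <= alpha
    df["direction"] = np.where(
        df["odds_ratio"] > 1, "enriched_in_phosphosites", "depleted_in_phosphosites"
    )
    df.loc[~tested, "direction"] = "never_observed"
    return df


def permute_phospho_labels(
    proteome: dict[str, str],
    sites: Sequence[PhosphoSite],
    seed: int,
    protein_ids: set[str] | None = None,
) -> list[PhosphoSite]:
    """Reassign phospho labels uniformly within each residue type.

    Keeps the per-residue-type site counts but redraws which S/T/Y positions
    carry them, the null used for type-I-error checks of
    :func:`substitution_enrichment`.
    """
    rng = np.random.default_rng(seed)
    ids = sorted(protein_ids) if protein_ids is not None else sorted(proteome)
    new_sites: list[PhosphoSite] = []
    for residue in PHOSPHO_RESIDUES:
        pool = [
            (pid, pos0 + 1)
            for pid in ids
            for pos0, aa in enumerate(proteome[pid])
            if aa == residue
        ]
        n = sum(1 for s in sites if s.residue == residue)
        if n > len(pool):
            raise ValueError(f"more {residue} sites than {residue} positions")
        chosen = rng.choice(len(pool), size=n, replace=False)
        for idx in chosen:
            pid, pos = pool[int(idx)]
            new_sites.append(PhosphoSite(pid, pos, residue, "experimental"))
    return new_sites
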