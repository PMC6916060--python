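"""Comparative statistics over repertoires and OGGs.

Covers the repertoire-level summaries (per-species intact / pseudogene /
truncated counts and pseudogene proportion), OGG-level descriptors (mean
pairwise similarity, per-species count variability), the hypothesis tests
used throughout (exact-permutation Mann-Whitney U, Pearson correlation),
and a pairwise Nei-Gojobori (NG86) dN/dS estimator with Jukes-Cantor
correction as the in-repo selective-pressure proxy (a maximum-likelihood
codon model run through an external tool is deliberately out of scope;
the analyses of interest are rank-level).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import ogg_mean_similarity
from .sequences import CODON_TO_AA, STOP_CODONS

# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

EXACT_MAX_N = 20  # exact permutation when combined sample size <= this


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact permutation p (all C(n, n_a) group assignments enumerated, ties
    handled with midranks) when the combined n <= 20; otherwise the
    normal approximation with tie correction.  Returns (U of the first
    group, p).  Identical pooled values give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    U = float(ranks[:na].sum() - na * (na + 1) / 2)
    if np.all(pooled == pooled[0]):
        return U, 1.0
    if na + nb <= EXACT_MAX_N:
        mu = na * nb / 2.0
        dev = abs(U - mu)
        count = total = 0
        for comb in itertools.combinations(range(na + nb), na):
            r = sum(ranks[i] for i in comb)
            u = r - na * (na + 1) / 2
            if abs(u - mu) >= dev - 1e-9:
                count += 1
            total += 1
        return U, count / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return U, float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the t-transform p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one variable")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# repertoire and OGG summaries
# ---------------------------------------------------------------------------

def repertoire_summary(calls: pd.DataFrame, habitat: dict[str, str] | None = None,
                       ogg_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-species intact / pseudogene / truncated counts and the
    pseudogene proportion = pseudogenes / (intact + pseudogenes +
    truncated); truncated genes count in the denominator."""
    need = {"species", "status"}
    if not need <= set(calls.columns):
        raise ValueError(f"calls table needs columns {need}")
    counts = calls.groupby(["species", "status"]).size().unstack(fill_value=0)
    for col in ("intact", "pseudogene", "truncated"):
        if col not in counts:
            counts[col] = 0
    out = counts[["intact", "pseudogene", "truncated"]].copy()
    total = out.sum(axis=1)
    out["pseudogene_proportion"] = np.where(total > 0, out["pseudogene"] / total, 0.0)
    if ogg_table is not None:
        ogg_n = (ogg_table[ogg_table["status"] == "intact"]
                 .groupby("species")["ogg_name"].nunique())
        out["ogg_count"] = ogg_n.reindex(out.index).fillna(0).astype(int)
    if habitat:
        out["habitat"] = [habitat.get(sp, "unknown") for sp in out.index]
    return out


def ogg_similarity(members: list[str]) -> float:
    """Mean pairwise identity among member proteins; NaN for < 2 members."""
    return ogg_mean_similarity(members)


def size_variability(ogg_table: pd.DataFrame, species: list[str]
                     ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-OGG (total intact count, per-species SD) and their Pearson
    correlation.  The SD uses the full zero-padded species vector with
    denominator n-1."""
    intact = ogg_table[ogg_table["status"] == "intact"]
    counts = (intact.groupby(["ogg_name", "species"]).size().unstack(fill_value=0)
              .reindex(columns=species, fill_value=0))
    frame = pd.DataFrame({
        "total": counts.sum(axis=1),
        "sd": counts.std(axis=1, ddof=1),
    })
    if len(frame) >= 3 and frame["total"].std() > 0 and frame["sd"].std() > 0:
        r, p = pearson(frame["total"], frame["sd"])
    else:
        r, p = float("nan"), float("nan")
    return frame, (r, p)


# ---------------------------------------------------------------------------
# NG86 pairwise dN/dS
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _codon_site_split(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; mutations to
    stop codons are excluded, each position contributes one site."""
    aa = CODON_TO_AA[codon]
    syn_sites = 0.0
    for pos in range(3):
        syn = non = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if CODON_TO_AA[mut] == aa:
                syn += 1
            else:
                non += 1
        if syn + non:
            syn_sites += syn / (syn + non)
    return syn_sites, 3.0 - syn_sites


def _codon_diff_split(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over mutational pathways; pathways through stop codons are
    skipped when any stop-free pathway exists."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def walk(skip_stops: bool):
        tallies = []
        for order in itertools.permutations(positions):
            cur, sd, nd, ok = c1, 0, 0, True
            for pos in order:
                nxt = cur[: pos] + c2[pos] + cur[pos + 1 :]
                if skip_stops and nxt in STOP_CODONS:
                    ok = False
                    break
                if CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                tallies.append((sd, nd))
        return tallies

    tallies = walk(skip_stops=True) or walk(skip_stops=False)
    sd = float(np.mean([t[0] for t in tallies]))
    nd = float(np.mean([t[1] for t in tallies]))
    return sd, nd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(seq1: str, seq2: str) -> tuple[float, float]:
    """(dN, dS) for an in-frame codon sequence pair (NG86 counting with
    Jukes-Cantor correction).  Codons containing gaps, ambiguity or stops
    are skipped pairwise."""
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("need equal-length in-frame sequences")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if (set(c1) | set(c2)) - set(_BASES):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s1, n1 = _codon_site_split(c1)
        s2, n2 = _codon_site_split(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _codon_diff_split(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no comparable codons")
    return _jc_correct(Nd / N), _jc_correct(Sd / S)


@dataclass
class OmegaEstimate:
    ogg: str
    omega: float  # NaN when undefined
    n_pairs: int  # usable pairs (dS > 0)
    flag: str = ""


def pairwise_omega(ogg_id: str, codon_seqs: dict[str, str]) -> OmegaEstimate:
    """OGG-level omega = median of pairwise dN/dS over members.

    Requires >= 3 sequences; pairs with dS = 0 are excluded (their ratio
    is undefined), and an OGG where every pair lacks synonymous change is
    flagged rather than assigned a value.
    """
    if len(codon_seqs) < 3:
        return OmegaEstimate(ogg_id, float("nan"), 0, "fewer than 3 sequences")
    ratios = []
    usable = 0
    for a, b in itertools.combinations(sorted(codon_seqs), 2):
        try:
            dn, ds = ng86_pair(codon_seqs[a], codon_seqs[b])
        except ValueError:
            continue
        if ds == 0 or not np.isfinite(ds):
            continue
        usable += 1
        ratios.append(dn / ds if np.isfinite(dn) else float("inf"))
    if not ratios:
        return OmegaEstimate(ogg_id, float("nan"), 0, "no pair with synonymous change")
    return OmegaEstimate(ogg_id, float(np.median(ratios)), usable)


def omega_correlates(omega: pd.DataFrame, ogg_table: pd.DataFrame,
                     events: pd.DataFrame | None = None) -> dict:
    """Correlations of per-OGG omega with intact count and with per-OGG
    gain/loss totals, plus the Class I vs II omega comparison.

    ``omega`` needs columns (ogg, omega); ``events`` (if given) columns
    (ogg, gains, losses).  Returns a dict of (r, p) / (U, p) results;
    undefined comparisons carry a 'flag' entry instead.
    """
    if events is not None and events.empty:
        raise ValueError("empty events table")
    out: dict[str, object] = {}
    om = omega.dropna(subset=["omega"]).set_index("ogg")
    intact_counts = (ogg_table[ogg_table["status"] == "intact"]
                     .groupby("ogg_name").size().rename("intact"))
    joined = om.join(intact_counts, how="inner")
    if len(joined) >= 3 and joined["omega"].std() > 0 and joined["intact"].std() > 0:
        out["omega_vs_intact"] = pearson(joined["intact"], joined["omega"])
    else:
        out["omega_vs_intact"] = ("flag", "undefined (constant or too few)")
    if events is not None:
        ev = events.set_index("ogg")
        j2 = om.join(ev, how="inner")
        for col in ("gains", "losses"):
            if len(j2) >= 3 and j2["omega"].std() > 0 and j2[col].std() > 0:
                out[f"omega_vs_{col}"] = pearson(j2[col], j2["omega"])
            else:
                out[f"omega_vs_{col}"] = ("flag", "undefined (constant or too few)")
    classes = ogg_table[["ogg_name", "class"]].drop_duplicates().set_index("ogg_name")
    jc = om.join(classes, how="inner")
    w1 = jc.loc[jc["class"] == "I", "omega"]
    w2 = jc.loc[jc["class"] == "II", "omega"]
    if len(w1) and len(w2):
        out["class1_vs_class2"] = mann_whitney(w1, w2)
    else:
        out["class1_vs_class2"] = ("flag", "one class empty")
    return out
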