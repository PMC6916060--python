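"""Gene gain/loss rate estimation on a dated species tree.

The model: on a branch of duration T (million years, MY) starting from A0
genes, gains and losses accrue in proportion to the current gene count with
per-gene per-MY rates beta (gain) and delta (loss),

    dg/dt = (A0 + g(t) - l(t)) * beta
    dl/dt = (A0 + g(t) - l(t)) * delta .

Writing G = g(T), L = l(T), the pair of ODEs inverts in closed form to

    beta  = G / ((G - L) T) * ln(1 + (G - L) / A0)
    delta = L / ((G - L) T) * ln(1 + (G - L) / A0)

with the continuous limit beta = G/(A0 T), delta = L/(A0 T) at G = L.

Per-branch A0, G and L come from an ancestral gene-content reconstruction:
orthologous-group (OGG) presence by Dollo parsimony (a group arises once,
may be lost repeatedly), copy numbers by Sankoff parsimony with unit cost
per copy gained or lost.  ``GeneContentModel`` packages the whole
procedure as a model object whose ``fit`` returns a results object with
per-branch estimates and a ``summary`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .trees import DatedSpeciesTree

__all__ = [
    "estimate_rates",
    "ode_forward_oracle",
    "reconstruct_ancestral",
    "count_branch_events",
    "summarize_rates",
    "GeneContentModel",
    "GainLossResults",
    "BranchEventCounts",
    "RateEstimate",
]


@dataclass
class BranchEventCounts:
    """Per-branch bookkeeping: A0 genes at branch start, G gained, L lost
    over duration T; OGG-level gains / contractions / complete losses."""

    branch: str
    A0: int
    G: int
    L: int
    T: float
    ogg_gains: int = 0
    ogg_contractions: int = 0
    ogg_losses: int = 0
    terminal: bool = False

    @property
    def end_count(self) -> int:
        return self.A0 + self.G - self.L


@dataclass
class RateEstimate:
    branch: str
    beta: float
    delta: float
    terminal: bool = False


def estimate_rates(counts: BranchEventCounts) -> RateEstimate:
    """Closed-form (beta, delta) from per-branch (A0, G, L, T).

    The G = L degenerate case uses the analytic limit; a branch losing its
    entire repertoire (end count 0 with G = 0) reports delta as +inf with
    a warning; end count 0 with G > 0 makes the logarithm undefined and
    raises.
    """
    A0, G, L, T = counts.A0, counts.G, counts.L, counts.T
    if A0 <= 0 or T <= 0:
        raise ValueError(f"branch {counts.branch}: need A0 > 0 and T > 0 (A0={A0}, T={T})")
    if G < 0 or L < 0:
        raise ValueError("event counts must be non-negative")
    net = G - L
    end = A0 + net
    if end < 0:
        raise ValueError(f"branch {counts.branch}: A0 + G - L = {end} < 0")
    if end == 0:
        if G > 0:
            raise ValueError(
                f"branch {counts.branch}: total loss with G={G} > 0 makes "
                "ln(1 + (G-L)/A0) undefined"
            )
        warnings.warn(f"branch {counts.branch}: complete repertoire loss, delta -> inf")
        return RateEstimate(counts.branch, 0.0, float("inf"), counts.terminal)
    if net == 0:
        return RateEstimate(counts.branch, G / (A0 * T), L / (A0 * T), counts.terminal)
    factor = np.log1p(net / A0) / (net * T)
    return RateEstimate(counts.branch, G * factor, L * factor, counts.terminal)


def ode_forward_oracle(beta: float, delta: float, A0: float, T: float,
                       rtol: float = 1e-12, atol: float = 1e-12) -> tuple[float, float]:
    """Numerically integrate the forward gain/loss ODEs; returns (G, L).

    Independent of the closed-form inversion: a plain initial-value solve
    of dg/dt = (A0+g-l)beta, dl/dt = (A0+g-l)delta from g(0)=l(0)=0.
    """
    if beta < 0 or delta < 0:
        raise ValueError("rates must be non-negative")
    if T == 0 or (beta == 0 and delta == 0):
        return 0.0, 0.0
    sol = solve_ivp(
        lambda t, y: [(A0 + y[0] - y[1]) * beta, (A0 + y[0] - y[1]) * delta],
        (0.0, T), [0.0, 0.0], method="DOP853", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    g, l = sol.y[:, -1]
    return float(g), float(l)


# ---------------------------------------------------------------------------
# ancestral content reconstruction
# ---------------------------------------------------------------------------

def _postorder(tree: DatedSpeciesTree):
    return list(tree.tree.postorder_node_iter())


def reconstruct_ancestral(tip_counts: pd.DataFrame, tree: DatedSpeciesTree) -> pd.DataFrame:
    """Reconstruct per-node OGG copy numbers on the species tree.

    Parameters
    ----------
    tip_counts :
        DataFrame species x OGG of non-negative integer copy numbers.
    tree :
        Dated species tree whose tip labels cover ``tip_counts.index``.

    Presence/absence follows Dollo parsimony: each OGG originates once at
    the MRCA of the tips carrying it and may only be lost below that node.
    Copy numbers at Dollo-present nodes minimise total |parent - child|
    change (Sankoff, unit cost per copy), ties resolved toward the
    smallest count.  Returns a DataFrame node-key x OGG (tips included).
    """
    taxa = tree.taxa
    missing = set(taxa) - set(tip_counts.index)
    if missing:
        raise ValueError(f"tip counts missing species: {sorted(missing)}")
    oggs = list(tip_counts.columns)
    n_ogg = len(oggs)
    tips = tip_counts.loc[:, oggs].to_numpy(dtype=int)
    if (tips < 0).any():
        raise ValueError("copy numbers must be non-negative")
    tip_row = {sp: i for i, sp in enumerate(tip_counts.index)}

    nodes = _postorder(tree)
    nid = {id(nd): i for i, nd in enumerate(nodes)}

    # Dollo presence ------------------------------------------------------
    below = np.zeros((len(nodes), n_ogg), dtype=int)  # present tips in subtree
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            below[i] = (tips[tip_row[nd.taxon.label]] > 0).astype(int)
        else:
            below[i] = sum(below[nid[id(ch)]] for ch in nd.child_nodes())
    total = below[nid[id(nodes[-1])]]  # root row (last in postorder)
    present = np.zeros((len(nodes), n_ogg), dtype=bool)
    for i, nd in enumerate(nodes):
        has_any = below[i] >= 1
        if nd.is_leaf():
            strict_anc = np.zeros(n_ogg, dtype=bool)
        else:
            child_max = np.max([below[nid[id(ch)]] for ch in nd.child_nodes()], axis=0)
            strict_anc = (below[i] == total) & (child_max == total) & (total > 0)
        present[i] = has_any & ~strict_anc

    # Sankoff copy numbers -------------------------------------------------
    cmax = int(tips.max(initial=0))
    S = cmax + 1
    dist = np.abs(np.arange(S)[:, None] - np.arange(S)[None, :]).astype(float)
    INF = 1e18
    cost = np.full((len(nodes), S, n_ogg), INF)
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            obs = tips[tip_row[nd.taxon.label]]
            cost[i][obs, np.arange(n_ogg)] = 0.0
        else:
            acc = np.zeros((S, n_ogg))
            for ch in nd.child_nodes():
                c = cost[nid[id(ch)]]
                # min over child state j of c[j] + |s - j|
                acc += (dist[:, :, None] + c[None, :, :]).min(axis=1)
            acc[0, present[i]] = INF       # Dollo-present: count >= 1
            acc[1:, ~present[i]] = INF     # Dollo-absent: count 0
            cost[i] = acc

    # backtrace (preorder)
    state = np.zeros((len(nodes), n_ogg), dtype=int)
    root_i = nid[id(nodes[-1])]
    state[root_i] = np.argmin(cost[root_i], axis=0)  # argmin picks smallest on tie
    for nd in reversed(nodes):  # preorder
        i = nid[id(nd)]
        for ch in nd.child_nodes():
            j = nid[id(ch)]
            total_cost = cost[j] + dist[state[i], :].T  # (S, n_ogg)
            state[j] = np.argmin(total_cost, axis=0)

    keys = [tree.node_key(nd) for nd in nodes]
    return pd.DataFrame(state, index=keys, columns=oggs)


def count_branch_events(content: pd.DataFrame, tree: DatedSpeciesTree,
                        count_mode: str = "genes") -> list[BranchEventCounts]:
    """Per-branch event counts from a reconstructed content matrix.

    ``count_mode='genes'`` counts gene copies (G = sum over OGGs of
    max(0, child - parent), L symmetric); ``'oggs'`` counts whole OGGs
    gained/lost.  OGG-level gains / contractions / complete losses are
    always reported alongside.
    """
    if count_mode not in ("genes", "oggs"):
        raise ValueError("count_mode must be 'genes' or 'oggs'")
    out = []
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent = content.loc[tree.node_key(nd.parent_node)].to_numpy()
        child = content.loc[tree.node_key(nd)].to_numpy()
        diff = child - parent
        ogg_gains = int((diff > 0).sum())
        ogg_contractions = int(((parent > child) & (child > 0)).sum())
        ogg_losses = int(((parent > 0) & (child == 0)).sum())
        if count_mode == "genes":
            G = int(np.maximum(diff, 0).sum())
            L = int(np.maximum(-diff, 0).sum())
            A0 = int(parent.sum())
        else:
            G = int(((parent == 0) & (child > 0)).sum())
            L = ogg_losses
            A0 = int((parent > 0).sum())
        out.append(BranchEventCounts(
            branch=tree.node_key(nd), A0=A0, G=G, L=L,
            T=tree.branch_duration(nd),
            ogg_gains=ogg_gains, ogg_contractions=ogg_contractions,
            ogg_losses=ogg_losses, terminal=nd.is_leaf(),
        ))
    return out


def per_ogg_events(content: pd.DataFrame, tree: DatedSpeciesTree) -> pd.DataFrame:
    """Total copy gains and losses per OGG summed over all branches of the
    reconstruction (columns: ogg, gains, losses)."""
    gains = np.zeros(content.shape[1], dtype=int)
    losses = np.zeros(content.shape[1], dtype=int)
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent = content.loc[tree.node_key(nd.parent_node)].to_numpy()
        child = content.loc[tree.node_key(nd)].to_numpy()
        diff = child - parent
        gains += np.maximum(diff, 0)
        losses += np.maximum(-diff, 0)
    return pd.DataFrame({"ogg": content.columns, "gains": gains, "losses": losses})


def summarize_rates(rates: list[RateEstimate], groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Arithmetic group means of terminal-branch rates.

    ``groups`` maps species -> group label (e.g. marine / terrestrial);
    ungrouped terminal branches fall into 'all' only.  Internal branches
    are excluded from means.
    """
    term = [r for r in rates if r.terminal and np.isfinite(r.delta)]
    rows = []
    labels = {"all": term}
    if groups:
        for g in sorted(set(groups.values())):
            labels[g] = [r for r in term if groups.get(r.branch) == g]
    for name, members in labels.items():
        if not members:
            rows.append({"group": name, "n": 0, "beta_mean": np.nan, "delta_mean": np.nan,
                         "flag": "empty group"})
            continue
        rows.append({
            "group": name, "n": len(members),
            "beta_mean": float(np.mean([r.beta for r in members])),
            "delta_mean": float(np.mean([r.delta for r in members])),
            "flag": "",
        })
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class GeneContentModel:
    """Birth-death gene-content model over a dated species tree.

    Parameters
    ----------
    tip_counts :
        DataFrame species x OGG of intact-gene copy numbers (the
        classifier's per-species OGG table).
    tree :
        DatedSpeciesTree with ages in MY.
    count_mode :
        'genes' (default): G and L count gene copies, matching rates
        defined as intact genes gained/lost per gene per MY; 'oggs'
        counts whole orthologous groups instead.
    """

    def __init__(self, tip_counts: pd.DataFrame, tree: DatedSpeciesTree,
                 count_mode: str = "genes"):
        self.tip_counts = tip_counts
        self.tree = tree
        self.count_mode = count_mode

    @classmethod
    def from_ogg_table(cls, ogg_table: pd.DataFrame, tree: DatedSpeciesTree,
                       count_mode: str = "genes") -> "GeneContentModel":
        """Build from a long-format OGG table with columns
        (ogg_name, species, gene_id, status); only intact genes count."""
        intact = ogg_table[ogg_table["status"] == "intact"]
        counts = (intact.groupby(["species", "ogg_name"]).size().unstack(fill_value=0))
        for sp in tree.taxa:
            if sp not in counts.index:
                counts.loc[sp] = 0
        return cls(counts.sort_index(), tree, count_mode)

    def fit(self) -> "GainLossResults":
        content = reconstruct_ancestral(self.tip_counts, self.tree)
        events = count_branch_events(content, self.tree, self.count_mode)
        rates = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ev in events:
                if ev.A0 == 0 or ev.T <= 0:
                    rates.append(RateEstimate(ev.branch, np.nan, np.nan, ev.terminal))
                    continue
                try:
                    rates.append(estimate_rates(ev))
                except ValueError:
                    rates.append(RateEstimate(ev.branch, np.nan, np.nan, ev.terminal))
        return GainLossResults(self, content, events, rates)


@dataclass
class GainLossResults:
    """Fitted per-branch gain/loss rates with the reconstruction behind them."""

    model: GeneContentModel
    content: pd.DataFrame
    events: list[BranchEventCounts] = field(repr=False)
    rates: list[RateEstimate] = field(repr=False)

    @property
    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.events]).set_index("branch")

    @property
    def rates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rates]).set_index("branch")

    def terminal_rates(self) -> pd.DataFrame:
        rf = self.rates_frame
        return rf[rf["terminal"]].drop(columns="terminal")

    def group_means(self, groups: dict[str, str]) -> pd.DataFrame:
        return summarize_rates(self.rates, groups)

    def summary(self) -> str:
        ef, rf = self.events_frame, self.rates_frame
        joined = ef.join(rf[["beta", "delta"]])
        lines = [
            "Gene gain/loss model (Dollo + Sankoff reconstruction, "
            f"count_mode={self.model.count_mode})",
            f"species: {len(self.model.tree.taxa)}   OGGs: {self.content.shape[1]}   "
            f"branches: {len(self.events)}",
            "",
            joined.to_string(
                float_format=lambda v: f"{v:.5f}",
                columns=["A0", "G", "L", "T", "ogg_gains", "ogg_contractions",
                         "ogg_losses", "beta", "delta"],
            ),
        ]
        return "\n".join(lines)
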