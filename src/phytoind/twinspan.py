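"""Divisive TWINSPAN-style classification and fidelity-based diagnostics.

Two-Way INdicator SPecies ANalysis classifies relevés by recursively
splitting them on the first axis of a correspondence analysis (CA) of a
binary *pseudospecies* expansion of the cover matrix: each species at cover
``c`` contributes one binary pseudospecies for every cut level ``<= c``
(nested), so abundance information enters an otherwise presence/absence
method.  Each division records the CA axis-1 eigenvalue and up to five
indicator pseudospecies — the pseudospecies whose relative frequencies
differ most between the two sides.  The procedure follows Hill's published
algorithm in structure; where the classic desktop implementations have
undocumented behaviour (misclassification handling, tie rules) this module
documents its own deterministic choices.

Diagnostic species of the resulting (or any externally supplied) groups are
detected with the phi coefficient of association computed from the 2x2
occurrence table, optionally equalised to a virtual design in which the
target group holds a fixed fraction of all plots, with a two-sided Fisher
exact test for significance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .releves import ReleveSet

logger = logging.getLogger(__name__)

DEFAULT_CUT_LEVELS = (0.0, 2.0, 5.0, 10.0, 20.0)
DEFAULT_MAX_LEVELS = 6
DEFAULT_MIN_GROUP = 5
#: divisions with a CA axis-1 eigenvalue below this are treated as noise
#: within a homogeneous group and not performed (division-quality floor)
DEFAULT_MIN_EIGENVALUE = 0.45
MAX_INDICATORS = 5
#: minimum between-side frequency difference for an indicator pseudospecies
MIN_INDICATOR_DIFF = 0.2
#: half-width of the borderline band around the CA centroid, as a fraction
#: of the maximum |score|; only borderline plots may be reassigned by
#: indicator scores
BORDERLINE_FRACTION = 0.05

CA_TOL = 1e-10
CA_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# pseudospecies


@dataclass
class PseudospeciesMatrix:
    """Binary plot x pseudospecies matrix with its cut levels.

    Column names are ``"<species>|<cut>"``; the level-0 pseudospecies is
    plain presence.
    """

    binary: pd.DataFrame
    cut_levels: tuple[float, ...]

    @property
    def plot_ids(self) -> list[str]:
        return list(self.binary.index)


def make_pseudospecies(
    rs: ReleveSet, cut_levels: tuple[float, ...] = DEFAULT_CUT_LEVELS
) -> PseudospeciesMatrix:
    """Expand covers into nested binary pseudospecies.

    A species at cover c is present in pseudospecies ``sp|k`` for every cut
    level k <= c; presence at a level implies presence at all lower levels.
    Cut levels must be strictly increasing and start at 0.
    """
    cuts = tuple(float(c) for c in cut_levels)
    if len(cuts) == 0 or cuts[0] != 0.0 or any(
        b <= a for a, b in zip(cuts, cuts[1:])
    ):
        raise ValueError(
            f"cut_levels must be strictly increasing and start at 0, got {cuts}"
        )
    covers = rs.covers
    cols: dict[str, np.ndarray] = {}
    vals = covers.to_numpy(dtype=float)
    present = np.isfinite(vals)
    for k, cut in enumerate(cuts):
        mask = present & (np.nan_to_num(vals, nan=-1.0) >= cut) if cut > 0 else present
        for j, sp in enumerate(covers.columns):
            col = mask[:, j]
            if col.any():
                cols[f"{sp}|{cut:g}"] = col.astype(np.int8)
    binary = pd.DataFrame(cols, index=covers.index)
    binary.index.name = "plot_id"
    return PseudospeciesMatrix(binary, cuts)


# ---------------------------------------------------------------------------
# correspondence analysis axis 1 (reciprocal averaging)


def ca_axis1(binary: pd.DataFrame) -> tuple[pd.Series, float]:
    """First CA axis of a binary matrix by reciprocal averaging.

    Power iteration on the row-score transition operator with the trivial
    (constant) axis deflated; tolerance 1e-10, at most 10^4 iterations.
    Returns (plot scores centred at the weighted centroid 0, eigenvalue).
    The orientation is fixed by an order-invariant rule: the species score
    largest in absolute value is made positive (ties: lexicographically
    smallest column name wins).
    """
    a = binary.to_numpy(dtype=float)
    n, m = a.shape
    r = a.sum(axis=1)
    c = a.sum(axis=0)
    if (r == 0).any():
        empty = binary.index[r == 0].tolist()
        raise ValueError(f"plots with zero pseudospecies: {empty}")
    keep = c > 0
    a = a[:, keep]
    c = c[keep]
    names = binary.columns[keep]
    total = r.sum()

    # order-invariant deterministic start: weight columns by their rank in
    # name-sorted order
    order = np.argsort(names.to_numpy())
    s = np.empty(len(names))
    s[order] = np.arange(len(names), dtype=float)
    x = (a @ s) / r

    def center(v: np.ndarray) -> np.ndarray:
        return v - (r @ v) / total

    x = center(x)
    norm = np.sqrt((r * x * x).sum() / total)
    if norm < 1e-300:  # degenerate start; perturb with squared ranks
        x = center((a @ (s**2)) / r)
        norm = np.sqrt((r * x * x).sum() / total)
        if norm < 1e-300:
            return pd.Series(np.zeros(n), index=binary.index), 0.0
    x /= norm

    eig = 0.0
    for _ in range(CA_MAX_ITER):
        u = (a.T @ x) / c
        x_new = center((a @ u) / r)
        eig = float((r * x * x_new).sum() / total)
        norm = np.sqrt((r * x_new * x_new).sum() / total)
        if norm < 1e-300:
            return pd.Series(np.zeros(n), index=binary.index), 0.0
        x_new /= norm
        if np.abs(x_new - x).max() < CA_TOL or np.abs(x_new + x).max() < CA_TOL:
            x = x_new
            break
        x = x_new

    u = (a.T @ x) / c
    j = int(np.lexsort((names.to_numpy(), -np.abs(u)))[0])
    if u[j] < 0:
        x = -x
    return pd.Series(x, index=binary.index), abs(eig)


# ---------------------------------------------------------------------------
# division tree


@dataclass
class DivisionNode:
    """One node of the TWINSPAN hierarchy.

    Internal nodes carry the CA axis-1 eigenvalue of their division, the
    per-plot split sign and up to five signed indicator pseudospecies;
    leaves carry a terminal group id.
    """

    plot_ids: list[str]
    eigenvalue: float | None = None
    indicators: list[tuple[str, int]] = field(default_factory=list)
    negative: "DivisionNode | None" = None
    positive: "DivisionNode | None" = None
    group_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.group_id is not None

    def leaves(self) -> list["DivisionNode"]:
        if self.is_leaf:
            return [self]
        return self.negative.leaves() + self.positive.leaves()

    def to_dict(self) -> dict:
        d: dict = {"plot_ids": list(self.plot_ids)}
        if self.is_leaf:
            d["group_id"] = self.group_id
        else:
            d["eigenvalue"] = self.eigenvalue
            d["indicators"] = [[n, s] for n, s in self.indicators]
            d["negative"] = self.negative.to_dict()
            d["positive"] = self.positive.to_dict()
        return d


@dataclass
class DivisionTree:
    root: DivisionNode
    cut_levels: tuple[float, ...]

    def terminal_groups(self) -> pd.Series:
        """plot_id -> terminal group id (leaves numbered depth-first,
        negative side first)."""
        mapping: dict[str, int] = {}
        for leaf in self.root.leaves():
            for p in leaf.plot_ids:
                mapping[p] = leaf.group_id
        return pd.Series(mapping, name="group")

    @property
    def n_groups(self) -> int:
        return len(self.root.leaves())

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"cut_levels": list(self.cut_levels), "tree": self.root.to_dict()},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _select_indicators(
    sub: np.ndarray, names: np.ndarray, neg: np.ndarray
) -> list[tuple[str, int]]:
    """Up to five pseudospecies maximising |freq(pos) - freq(neg)|."""
    n_neg, n_pos = int(neg.sum()), int((~neg).sum())
    if n_neg == 0 or n_pos == 0:
        return []
    f_neg = sub[neg].sum(axis=0) / n_neg
    f_pos = sub[~neg].sum(axis=0) / n_pos
    d = f_pos - f_neg
    order = np.lexsort((names, -np.abs(d)))
    out = []
    for j in order[:MAX_INDICATORS]:
        if abs(d[j]) < MIN_INDICATOR_DIFF:
            break
        out.append((str(names[j]), 1 if d[j] > 0 else -1))
    return out


def _divide(
    binary: pd.DataFrame,
    plots: list[str],
    level: int,
    max_levels: int,
    min_group: int,
    min_eigenvalue: float,
    counter: list[int],
) -> DivisionNode:
    node = DivisionNode(plot_ids=list(plots))
    if level >= max_levels or len(plots) < 2 * min_group:
        node.group_id = counter[0]
        counter[0] += 1
        return node

    sub = binary.loc[plots]
    sub = sub.loc[:, sub.sum(axis=0) > 0]
    scores, eig = ca_axis1(sub)
    # eig == 1 happens only for fully disjoint blocks (perfect separation);
    # still a valid division.  a low eigenvalue means the group has no real
    # compositional structure left, so dividing it would cut noise.
    if eig < min_eigenvalue or eig > 1 + 1e-9 or scores.abs().max() == 0:
        node.group_id = counter[0]
        counter[0] += 1
        return node

    # centroid split: the weighted centroid is 0 after centring; a plot
    # exactly at the centroid goes to the negative side
    neg = scores.to_numpy() <= 0.0

    arr = sub.to_numpy(dtype=float)
    names = sub.columns.to_numpy()
    indicators = _select_indicators(arr, names, neg)

    # borderline refinement: plots in a narrow band around the centroid may
    # be moved to the side their indicator score prefers
    if indicators:
        sign = np.array([s for _, s in indicators], dtype=float)
        cols = [list(sub.columns).index(n) for n, _ in indicators]
        ind_score = arr[:, cols] @ sign
        band = BORDERLINE_FRACTION * float(np.abs(scores.to_numpy()).max())
        borderline = np.abs(scores.to_numpy()) <= band
        refined = np.where(
            borderline & (ind_score != 0), ind_score < 0, neg
        )
        if refined.any() and (~refined).any():
            neg = refined

    if neg.sum() < min_group or (~neg).sum() < min_group:
        node.group_id = counter[0]
        counter[0] += 1
        return node

    node.eigenvalue = eig
    node.indicators = indicators
    neg_plots = [p for p, m in zip(plots, neg) if m]
    pos_plots = [p for p, m in zip(plots, neg) if not m]
    node.negative = _divide(
        binary, neg_plots, level + 1, max_levels, min_group, min_eigenvalue, counter
    )
    node.positive = _divide(
        binary, pos_plots, level + 1, max_levels, min_group, min_eigenvalue, counter
    )
    return node


def twinspan(
    psm: PseudospeciesMatrix,
    max_levels: int = DEFAULT_MAX_LEVELS,
    min_group: int = DEFAULT_MIN_GROUP,
    min_eigenvalue: float = DEFAULT_MIN_EIGENVALUE,
) -> DivisionTree:
    """Recursive CA divisions of a pseudospecies matrix.

    A node is divided while the division keeps both sides >= ``min_group``,
    the depth stays below ``max_levels`` and the division's CA eigenvalue
    reaches ``min_eigenvalue``; otherwise it becomes a terminal group.  Deterministic given the input; permuting plot order
    changes at most group numbering, never the partition.
    """
    binary = psm.binary
    rowsums = binary.sum(axis=1)
    if (rowsums == 0).any():
        raise ValueError(
            f"plots with zero pseudospecies: {binary.index[rowsums == 0].tolist()}"
        )
    counter = [1]
    root = _divide(
        binary, list(binary.index), 0, max_levels, min_group, min_eigenvalue, counter
    )
    return DivisionTree(root, psm.cut_levels)


# ---------------------------------------------------------------------------
# fidelity (phi) and the synoptic table


def _phi(N: float, Np: float, n: float, np_: float) -> float:
    num = N * np_ - n * Np
    denom = n * Np * (N - n) * (N - Np)
    if denom <= 0:
        # a species present in every plot (n = N) shows no association:
        # the numerator vanishes too, and phi is defined as 0; any other
        # degenerate margin leaves phi undefined
        return 0.0 if num == 0 else float("nan")
    return num / np.sqrt(denom)


def fidelity(
    presence: pd.DataFrame | ReleveSet,
    groups: pd.Series | dict,
    equalize: bool = True,
    target_fraction: float = 0.5,
) -> pd.DataFrame:
    """Phi fidelity of every species to every group.

    ``presence`` is a boolean plot x species frame (or a ReleveSet, whose
    presence matrix is used).  phi = (N n_p - n N_p) / sqrt(n N_p (N - n)
    (N - N_p)) from the occurrence counts N (plots), N_p (plots in group),
    n (species occurrences), n_p (occurrences in group).  With ``equalize``
    the counts are first rescaled to a virtual design in which the target
    group holds ``target_fraction`` of all plots, removing the dependence
    of phi on group size.  p-values come from a two-sided Fisher exact test
    on the raw (unequalised) 2x2 table.

    Returns a tidy frame with columns species, group, N, N_p, n, n_p, phi,
    p_value.  Species absent from every plot are skipped with a warning.
    """
    if isinstance(presence, ReleveSet):
        presence = presence.presence()
    groups = pd.Series(groups)
    common = presence.index.intersection(groups.index)
    presence = presence.loc[common]
    groups = groups.loc[common]
    labels = sorted(groups.unique(), key=str)
    if len(labels) < 2:
        raise ValueError("fidelity requires >= 2 groups")
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")

    N = len(presence)
    pres = presence.to_numpy(dtype=bool)
    n_all = pres.sum(axis=0)
    skipped = [sp for sp, cnt in zip(presence.columns, n_all) if cnt == 0]
    if skipped:
        logger.warning("fidelity: %d species absent everywhere, skipped", len(skipped))

    rows = []
    for label in labels:
        in_g = (groups == label).to_numpy()
        Np = int(in_g.sum())
        np_vec = pres[in_g].sum(axis=0)
        for j, sp in enumerate(presence.columns):
            n = int(n_all[j])
            if n == 0:
                continue
            np_ = int(np_vec[j])
            if equalize:
                Np_e = target_fraction * N
                np_e = (np_ / Np) * Np_e if Np else 0.0
                out_rate = (n - np_) / (N - Np) if N > Np else 0.0
                n_e = np_e + out_rate * (N - Np_e)
                phi = _phi(N, Np_e, n_e, np_e)
            else:
                phi = _phi(N, Np, n, np_)
            table = [[np_, Np - np_], [n - np_, (N - Np) - (n - np_)]]
            _, p = fisher_exact(table, alternative="two-sided")
            rows.append(
                {
                    "species": sp,
                    "group": label,
                    "N": N,
                    "N_p": Np,
                    "n": n,
                    "n_p": np_,
                    "phi": phi,
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def synoptic_table(
    rs: ReleveSet | pd.DataFrame,
    groups: pd.Series | dict,
    fidelity_table: pd.DataFrame,
    alpha: float = 0.05,
    phi_threshold: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage-occurrence synoptic table with diagnostic-species flags.

    Cell = 100 * occurrences in group / plots in group.  A species is
    flagged diagnostic for its best group (largest phi) when BOTH p_value <
    alpha and phi >= phi_threshold hold there.

    Returns (percent table species x groups, diagnostics frame with one row
    per species: best group, phi, p_value, diagnostic flag).
    """
    presence = rs.presence() if isinstance(rs, ReleveSet) else rs
    groups = pd.Series(groups)
    common = presence.index.intersection(groups.index)
    presence = presence.loc[common]
    groups = groups.loc[common]
    labels = sorted(groups.unique(), key=str)

    pct = pd.DataFrame(index=presence.columns, columns=labels, dtype=float)
    for label in labels:
        sub = presence[(groups == label).reindex(presence.index, fill_value=False)]
        pct[label] = 100.0 * sub.sum(axis=0) / len(sub)
    pct.index.name = "species"

    fid = fidelity_table.dropna(subset=["phi"])
    best = fid.loc[fid.groupby("species")["phi"].idxmax()].set_index("species")
    diag = pd.DataFrame(
        {
            "best_group": best["group"],
            "phi": best["phi"],
            "p_value": best["p_value"],
        }
    )
    diag["diagnostic"] = (diag["p_value"] < alpha) & (diag["phi"] >= phi_threshold)
    diag = diag.reindex(pct.index)
    diag["diagnostic"] = diag["diagnostic"].eq(True)  # NaN (unseen) -> False
    return pct, diag
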