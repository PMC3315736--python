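"""Selection of phenotype-divergent animal groups under a co-ancestry
constraint.

Candidates carry an estimated breeding value (EBV, here predicted
transmitting ability for calving interval, in days). Two disjoint groups of
equal size are built greedily: the low group is seeded with the
minimum-EBV animal and grown by repeatedly adding the candidate with the
best (lowest) index, a 60:40 weighted combination of the candidate's
standardized EBV and its mean standardized additive relationship to the
animals already selected. The high group is then built the same way from
the remaining candidates, seeded with the maximum-EBV animal and with the
sign of the merit term flipped. Penalising relatedness keeps many paternal
half-sib lines represented in each pool.

Relationships are Wright's numerator relationships from the pedigree
(tabular method); co-ancestry (kinship) is half the relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateInputError, PedigreeError

__all__ = [
    "standardize",
    "numerator_relationship_matrix",
    "IndexWeights",
    "SelectionResult",
    "select_divergent_groups",
    "group_summary",
]


def standardize(values) -> np.ndarray:
    """z-scores with population (ddof=0) normalisation: mean 0, variance 1."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ArgumentError("need a 1-d vector with at least two values")
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("constant vector cannot be standardized")
    return (x - x.mean()) / sd


def _topological_order(ped: pd.DataFrame) -> list[str]:
    """Order ids so parents precede offspring; raises on cycles."""
    parents = {row.id: [p for p in (row.sire, row.dam) if pd.notna(p)]
               for row in ped.itertuples()}
    known = set(parents)
    for pid, ps in parents.items():
        for p in ps:
            if p not in known:
                raise PedigreeError(f"unknown parent id {p!r} of {pid!r}")
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(node: str, stack: list[str]) -> None:
        st = state.get(node, 0)
        if st == 1:
            raise PedigreeError(
                f"pedigree cycle involving {node!r}: {' -> '.join(stack)}")
        if st == 2:
            return
        state[node] = 1
        for p in parents[node]:
            visit(p, stack + [p])
        state[node] = 2
        order.append(node)

    for pid in parents:
        visit(pid, [pid])
    return order


def numerator_relationship_matrix(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Wright's numerator relationship matrix A by the tabular method.

    ``pedigree`` has columns ``id, sire, dam`` (parents NaN when unknown).
    Founders get diagonal 1 and off-diagonal 0; for each animal in
    parent-first order ``a_ij = (a_{sire,j} + a_{dam,j}) / 2`` (unknown
    parents contribute 0) and ``a_ii = 1 + a_{sire,dam} / 2``.
    """
    ped = pedigree.copy()
    if ped["id"].duplicated().any():
        raise PedigreeError("duplicate animal ids in pedigree")
    order = _topological_order(ped)
    idx = {aid: i for i, aid in enumerate(order)}
    rows = ped.set_index("id")
    n = len(order)
    A = np.zeros((n, n))
    for aid in order:
        i = idx[aid]
        s, d = rows.loc[aid, "sire"], rows.loc[aid, "dam"]
        si = idx[s] if pd.notna(s) else None
        di = idx[d] if pd.notna(d) else None
        contrib = np.zeros(n)
        if si is not None:
            contrib += A[si]
        if di is not None:
            contrib += A[di]
        A[i, :i] = contrib[:i] / 2.0
        A[:i, i] = A[i, :i]
        inbreeding = A[si, di] / 2.0 if (si is not None and di is not None) \
            else 0.0
        A[i, i] = 1.0 + inbreeding
    # return in the input id order
    perm = [idx[aid] for aid in ped["id"]]
    A = A[np.ix_(perm, perm)]
    ids = list(ped["id"])
    return pd.DataFrame(A, index=ids, columns=ids)


@dataclass(frozen=True)
class IndexWeights:
    """Weights of the selection index: merit vs relatedness (60:40)."""

    w_ebv: float = 0.6
    w_rel: float = 0.4

    def __post_init__(self):
        if self.w_ebv < 0 or self.w_rel < 0:
            raise ArgumentError("index weights must be non-negative")
        if abs(self.w_ebv + self.w_rel - 1.0) > 1e-9:
            raise ArgumentError("index weights must sum to 1")


@dataclass
class SelectionResult:
    low_group: list
    high_group: list
    trace: pd.DataFrame = field(repr=False)

    def groups(self) -> dict[str, list]:
        return {"low": self.low_group, "high": self.high_group}


def _greedy_group(ids: np.ndarray, z_ebv: np.ndarray, z_rel: np.ndarray,
                  available: np.ndarray, size: int, sign: float,
                  weights: IndexWeights, group_name: str,
                  trace: list) -> list[int]:
    """Grow one group greedily; returns selected positional indices."""
    merit = sign * z_ebv
    avail = available.copy()
    # seed: extreme-merit animal, ties broken by lowest id
    cand = np.flatnonzero(avail)
    seed_order = cand[np.lexsort((ids[cand].astype(str), merit[cand]))]
    seed = int(seed_order[0])
    selected = [seed]
    avail[seed] = False
    trace.append({"group": group_name, "step": 0, "id": ids[seed],
                  "score": np.nan})
    rel_sum = z_rel[:, seed].astype(float).copy()
    for step in range(1, size):
        cand = np.flatnonzero(avail)
        score = (weights.w_ebv * merit[cand]
                 + weights.w_rel * rel_sum[cand] / len(selected))
        pick_order = cand[np.lexsort((ids[cand].astype(str), score))]
        best = int(pick_order[0])
        trace.append({"group": group_name, "step": step, "id": ids[best],
                      "score": float(score[np.searchsorted(
                          cand, best)])})
        selected.append(best)
        avail[best] = False
        rel_sum += z_rel[:, best]
    available[selected] = False
    return selected


def select_divergent_groups(animals: pd.DataFrame, A: pd.DataFrame,
                            size: int,
                            weights: IndexWeights = IndexWeights()
                            ) -> SelectionResult:
    """Choose two disjoint EBV-divergent groups, penalising co-ancestry.

    Parameters
    ----------
    animals
        Candidate table with columns ``id`` and ``ebv``.
    A
        Numerator relationship matrix over (at least) the candidates,
        indexed by animal id.
    size
        Animals per group.
    weights
        Index weights, default 60:40 merit:relatedness.

    Returns
    -------
    :class:`SelectionResult` with ordered low/high id lists and a per-step
    trace of the chosen candidate's index score (NaN for group seeds).
    """
    if size < 1:
        raise ArgumentError("group size must be >= 1")
    if len(animals) < 2 * size:
        raise ArgumentError(
            f"need at least {2 * size} candidates, got {len(animals)}")
    ids = animals["id"].to_numpy()
    z_ebv = standardize(animals["ebv"].to_numpy())
    a = A.loc[ids, ids].to_numpy()
    off = a[np.triu_indices_from(a, k=1)]
    sd = off.std()
    if sd == 0:  # mutually unrelated candidates: relatedness is uninformative
        z_rel = np.zeros_like(a)
    else:
        z_rel = (a - off.mean()) / sd
    np.fill_diagonal(z_rel, 0.0)  # self-relationship never enters the index

    available = np.ones(len(ids), dtype=bool)
    trace: list[dict] = []
    low = _greedy_group(ids, z_ebv, z_rel, available, size, +1.0,
                        weights, "low", trace)
    high = _greedy_group(ids, z_ebv, z_rel, available, size, -1.0,
                         weights, "high", trace)
    return SelectionResult(
        low_group=[ids[i] for i in low],
        high_group=[ids[i] for i in high],
        trace=pd.DataFrame(trace),
    )


def _mean_pairwise(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    return float(a[np.triu_indices(n, k=1)].mean())


def group_summary(result: SelectionResult, A: pd.DataFrame,
                  animals: pd.DataFrame) -> pd.DataFrame:
    """Per-group EBV and co-ancestry summary (plus the between-group row).

    Co-ancestry (kinship) is ``a_ij / 2``, reported in percent. Sire-line
    counts use the ``sire`` column when present.
    """
    info = animals.set_index("id")
    rows = []
    for name, members in result.groups().items():
        if not members:
            raise ArgumentError(f"{name} group is empty")
        ebv = info.loc[members, "ebv"].to_numpy(dtype=float)
        sub = A.loc[members, members].to_numpy()
        n_sires = (info.loc[members, "sire"].nunique(dropna=True)
                   if "sire" in info.columns else np.nan)
        rows.append({
            "group": name, "n": len(members),
            "mean_ebv": float(ebv.mean()),
            "sd_ebv": float(ebv.std(ddof=1)) if len(ebv) > 1 else 0.0,
            "mean_coancestry_pct": 100.0 * _mean_pairwise(sub) / 2.0,
            "n_sire_lines": n_sires,
        })
    between = A.loc[result.low_group, result.high_group].to_numpy()
    rows.append({
        "group": "between", "n": between.size,
        "mean_ebv": np.nan, "sd_ebv": np.nan,
        "mean_coancestry_pct": 100.0 * float(between.mean()) / 2.0,
        "n_sire_lines": np.nan,
    })
    return pd.DataFrame(rows)
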