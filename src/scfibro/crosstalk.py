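"""Ligand-receptor interaction scoring with a permutation test.

For a ligand-receptor pair and an ordered (sender, receiver) cluster pair
the interaction score is the mean of two averages on log-normalized data:

    score = ( mean ligand expression over sender cells
            + mean receptor expression over receiver cells ) / 2

Pairs where the ligand is detected (value > 0) in fewer than ``min_frac`` of
sender cells, or the receptor in fewer than ``min_frac`` of receiver cells,
are reported with p = 1 and an ``excluded`` flag. For the rest, cluster
labels of all retained cells are shuffled ``n_perm`` times and

    p = (1 + #{permuted score >= observed}) / (n_perm + 1),

with BH q-values across the reported (non-excluded) rows. This is the
mean-of-means / label-shuffling convention popularized by CellPhoneDB.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "interaction_score",
    "LigandReceptorPermutation",
    "permutation_pvalues",
    "export_dotplot_table",
]


def _labels_of(assign) -> pd.Series:
    labels = getattr(assign, "final", assign)
    labels = pd.Series(labels)
    return labels[labels != -1]


def interaction_score(expr: pd.DataFrame, assign, ligand: str, receptor: str,
                      sender, receiver) -> float:
    """Observed interaction score for one (pair, sender, receiver) combo."""
    labels = _labels_of(assign)
    for g in (ligand, receptor):
        if g not in expr.columns:
            raise KeyError(f"gene {g!r} absent from the expression matrix")
    s_cells = labels.index[labels == sender]
    r_cells = labels.index[labels == receiver]
    if len(s_cells) == 0 or len(r_cells) == 0:
        raise ValueError("sender and receiver clusters must be non-empty")
    return float((expr.loc[s_cells, ligand].mean()
                  + expr.loc[r_cells, receptor].mean()) / 2.0)


class LigandReceptorPermutation(BaseEstimator):
    """Permutation test over all directed cluster pairs and database pairs.

    ``fit(expr, assign, database)`` computes the full interaction table in
    ``table_`` with columns ligand, receptor, sender, receiver, score,
    frac_expressing_ligand, frac_expressing_receptor, excluded, missing_gene,
    p, q. Deterministic given ``random_state``.
    """

    def __init__(self, n_perm: int = 1000, min_frac: float = 0.1,
                 random_state: int = 0):
        self.n_perm = n_perm
        self.min_frac = min_frac
        self.random_state = random_state

    def fit(self, expr: pd.DataFrame, assign,
            database: pd.DataFrame) -> "LigandReceptorPermutation":
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if database.empty:
            raise ValueError("ligand-receptor database is empty")
        labels = _labels_of(assign)
        clusters = sorted(labels.unique())
        if len(clusters) < 2:
            raise ValueError("need at least 2 clusters")
        rng = np.random.default_rng(self.random_state)

        present = set(expr.columns)
        pairs = list(database[["ligand", "receptor"]].itertuples(index=False))
        genes_needed = sorted({g for p in pairs for g in p if g in present})
        gene_pos = {g: i for i, g in enumerate(genes_needed)}
        V = expr.loc[labels.index, genes_needed].to_numpy(dtype=float)
        codes = pd.Categorical(labels, categories=clusters).codes
        k = len(clusters)
        counts = np.bincount(codes, minlength=k).astype(float)

        def cluster_means(code_vec: np.ndarray) -> np.ndarray:
            sums = np.zeros((k, V.shape[1]))
            np.add.at(sums, code_vec, V)
            return sums / counts[:, None]

        M = cluster_means(codes)
        F = np.zeros((k, V.shape[1]))
        np.add.at(F, codes, (V > 0).astype(float))
        F /= counts[:, None]

        rows = []
        combos = []  # (row_index, lig_idx, rec_idx, s_idx, r_idx, obs)
        for lig, rec in pairs:
            missing = lig not in present or rec not in present
            for si, s in enumerate(clusters):
                for ri, r in enumerate(clusters):
                    row = {"ligand": lig, "receptor": rec, "sender": s,
                           "receiver": r, "missing_gene": missing}
                    if missing:
                        row.update(score=np.nan, frac_expressing_ligand=np.nan,
                                   frac_expressing_receptor=np.nan,
                                   excluded=True, p=1.0)
                    else:
                        li, gi = gene_pos[lig], gene_pos[rec]
                        score = (M[si, li] + M[ri, gi]) / 2.0
                        fl, fr = F[si, li], F[ri, gi]
                        excluded = fl < self.min_frac or fr < self.min_frac
                        row.update(score=score, frac_expressing_ligand=fl,
                                   frac_expressing_receptor=fr,
                                   excluded=excluded, p=1.0)
                        if not excluded:
                            combos.append((len(rows), li, gi, si, ri, score))
                    rows.append(row)

        if combos:
            idx = np.array([c[0] for c in combos])
            li = np.array([c[1] for c in combos])
            gi = np.array([c[2] for c in combos])
            si = np.array([c[3] for c in combos])
            ri = np.array([c[4] for c in combos])
            obs = np.array([c[5] for c in combos])
            ge = np.zeros(len(combos))
            for _ in range(self.n_perm):
                Mp = cluster_means(rng.permutation(codes))
                perm = (Mp[si, li] + Mp[ri, gi]) / 2.0
                ge += perm >= obs
            p = (1.0 + ge) / (self.n_perm + 1.0)
            for j, row_i in enumerate(idx):
                rows[row_i]["p"] = p[j]

        table = pd.DataFrame(rows)
        table["q"] = np.nan
        tested = ~table["excluded"]
        if tested.any():
            table.loc[tested, "q"] = multipletests(
                table.loc[tested, "p"], method="fdr_bh")[1]
        self.table_ = table
        return self


def permutation_pvalues(expr: pd.DataFrame, assign, database: pd.DataFrame,
                        n_perm: int = 1000, min_frac: float = 0.1,
                        seed: int = 0) -> pd.DataFrame:
    """Full interaction table; see :class:`LigandReceptorPermutation`."""
    model = LigandReceptorPermutation(n_perm=n_perm, min_frac=min_frac,
                                      random_state=seed)
    return model.fit(expr, assign, database).table_


def export_dotplot_table(table: pd.DataFrame, senders=None,
                         receivers=None) -> pd.DataFrame:
    """Long-format export of the quantities a dot plot encodes.

    Columns: ``pair`` (``ligand->receptor``), ``direction``
    (``sender->receiver``), ``score``, ``p``. Optional sender/receiver
    cluster filters.
    """
    sub = table
    if senders is not None:
        sub = sub[sub["sender"].isin(list(senders))]
    if receivers is not None:
        sub = sub[sub["receiver"].isin(list(receivers))]
    out = pd.DataFrame({
        "pair": sub["ligand"].astype(str) + "->" + sub["receptor"].astype(str),
        "direction": sub["sender"].astype(str) + "->"
        + sub["receiver"].astype(str),
        "score": sub["score"],
        "p": sub["p"],
    })
    return out.reset_index(drop=True)
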