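"""Pedigree handling and additive genetic relatedness.

The animal-model random effect in the phenotype regression has covariance
proportional to the numerator relationship matrix ``A = 2 * Phi``, where
``Phi`` is the kinship matrix: ``phi_xy`` is the probability that one allele
sampled from x and one from y are identical by descent.  ``Phi`` is computed
with the classical recursion over a pedigree sorted so parents precede
offspring:

    phi_xx = 1/2 * (1 + phi_{sire(x), dam(x)})
    phi_xy = 1/2 * (phi_{sire(x), y} + phi_{dam(x), y})   for y earlier than x

Unknown parents are founders and contribute zero kinship; inbreeding is
handled exactly by the recursion (diagonal entries of A may exceed 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "RelatednessMatrix", "kinship_matrix", "relatedness_matrix"]

UNKNOWN = ""


@dataclass(frozen=True)
class Pedigree:
    """Pedigree records ``(id, sire, dam)`` with "" for unknown parents."""

    records: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pedigree ids: {dupes}")

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def parents(self) -> dict[str, tuple[str, str]]:
        return {r[0]: (r[1], r[2]) for r in self.records}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        recs = []
        for _, row in df.iterrows():
            sire = "" if pd.isna(row["sire"]) else str(row["sire"])
            dam = "" if pd.isna(row["dam"]) else str(row["dam"])
            recs.append((str(row["id"]), sire, dam))
        return cls(tuple(recs))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["id", "sire", "dam"])

    def topological_order(self) -> list[str]:
        """Ids sorted parents-first; raises on cyclic pedigrees.

        Parents that never appear as records are implicit founders and are
        included in the returned order.
        """
        parents = self.parents()
        all_ids = list(parents)
        implicit = [
            p
            for pair in parents.values()
            for p in pair
            if p != UNKNOWN and p not in parents
        ]
        for p in dict.fromkeys(implicit):
            parents[p] = (UNKNOWN, UNKNOWN)
            all_ids.append(p)

        # Kahn's algorithm on the parent -> child DAG
        n_pending = {
            i: sum(1 for p in parents[i] if p != UNKNOWN) for i in all_ids
        }
        children: dict[str, list[str]] = {i: [] for i in all_ids}
        for i in all_ids:
            for p in parents[i]:
                if p != UNKNOWN:
                    children[p].append(i)
        queue = [i for i in all_ids if n_pending[i] == 0]
        order = []
        while queue:
            i = queue.pop()
            order.append(i)
            for ch in children[i]:
                n_pending[ch] -= 1
                if n_pending[ch] == 0:
                    queue.append(ch)
        if len(order) != len(all_ids):
            cyclic = sorted(i for i in all_ids if n_pending[i] > 0)
            raise ValueError(f"pedigree contains a cycle involving: {cyclic}")
        return order


@dataclass
class RelatednessMatrix:
    """Additive relatedness A = 2 * kinship, with its id ordering."""

    ids: list[str]
    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ValueError("A must be square over ids")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("A must be symmetric")
        if np.any(np.diag(self.A) < 1.0 - 1e-9):
            raise ValueError("diagonal of A must be >= 1")

    def subset(self, subjects: list[str]) -> "RelatednessMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        missing = [s for s in subjects if s not in pos]
        if missing:
            raise KeyError(f"subjects not in relatedness matrix: {missing}")
        idx = np.array([pos[s] for s in subjects])
        return RelatednessMatrix(ids=list(subjects), A=self.A[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.ids, columns=self.ids)


def kinship_matrix(ped: Pedigree, subjects: list[str] | None = None) -> pd.DataFrame:
    """Kinship matrix Phi over ``subjects`` (default: all pedigree ids).

    The full pedigree (including implicit founders) is traversed so that
    ancestors outside ``subjects`` still contribute.
    """
    order = ped.topological_order()
    parents = ped.parents()
    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for x in order:
        ix = pos[x]
        sire, dam = parents.get(x, (UNKNOWN, UNKNOWN))
        isire = pos[sire] if sire != UNKNOWN else None
        idam = pos[dam] if dam != UNKNOWN else None
        phi_sd = phi[isire, idam] if isire is not None and idam is not None else 0.0
        phi[ix, ix] = 0.5 * (1.0 + phi_sd)
        # kinship with everyone processed before x
        row = np.zeros(n)
        if isire is not None:
            row += phi[isire]
        if idam is not None:
            row += phi[idam]
        row *= 0.5
        mask = np.arange(n) != ix
        done = phi.diagonal() > 0  # already-processed individuals
        upd = mask & done
        phi[ix, upd] = row[upd]
        phi[upd, ix] = row[upd]
    full = pd.DataFrame(phi, index=order, columns=order)
    if subjects is None:
        subjects = ped.ids
    missing = [s for s in subjects if s not in pos]
    if missing:
        raise KeyError(f"subjects absent from pedigree: {missing}")
    return full.loc[subjects, subjects]


def relatedness_matrix(phi: pd.DataFrame) -> RelatednessMatrix:
    """A = 2 * Phi with the id ordering of ``phi`` preserved."""
    return RelatednessMatrix(ids=list(phi.index), A=2.0 * phi.to_numpy())
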