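"""Score signatures against ranked drug-perturbation profiles.

Conventions (used everywhere, asserted in tests):

* rank 1 = the gene most up-regulated by the treatment;
* the reflected rank ``r~ = n + 1 - r`` maps "near the top" to "near the
  bottom" and is how down-regulation and negative matching are expressed.

A positive match pools the raw ranks of the signature's up genes with the
reflected ranks of its down genes into one rank-product statistic: a
compound that pushes the up genes toward the top and the down genes toward
the bottom of its ranking yields a small pooled product and a small p.  The
negative match swaps the roles, probing compounds that oppose the signature.

Compounds usually have several treatment instances (cell line x dose);
per-compound evidence is combined across instances with Fisher's method,
treating instances as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .errors import ValidationError
from .io_formats import ProfileMatrix
from .rankprod import DEFAULT_BUDGET, RankProductResult, rankprod_pvalue
from .signatures import Signature, SignaturePanel

__all__ = [
    "RankedProfile",
    "ConnectivityResult",
    "CompoundSignatureScore",
    "rank_profile",
    "rank_matrix",
    "connectivity_score",
    "aggregate_instances",
    "score_panel",
]


@dataclass(frozen=True)
class RankedProfile:
    """One treatment instance's gene ranking (1 = most up-regulated)."""

    instance_id: str
    compound_id: str
    cell_line: str
    n: int
    rank_of: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.rank_of) != self.n:
            raise ValidationError(
                f"instance {self.instance_id!r}: {len(self.rank_of)} ranks "
                f"for universe of {self.n}"
            )
        if sorted(self.rank_of.values()) != list(range(1, self.n + 1)):
            raise ValidationError(
                f"instance {self.instance_id!r}: ranks are not a permutation of 1..{self.n}"
            )

    def reversed(self) -> "RankedProfile":
        """The profile with every rank reflected (r -> n + 1 - r)."""
        return RankedProfile(
            instance_id=self.instance_id,
            compound_id=self.compound_id,
            cell_line=self.cell_line,
            n=self.n,
            rank_of={g: self.n + 1 - r for g, r in self.rank_of.items()},
        )


@dataclass(frozen=True)
class ConnectivityResult:
    """Directional match p-values of one signature against one instance."""

    signature_name: str
    instance_id: str
    compound_id: str
    k_up: int
    k_down: int
    p_pos: float
    p_neg: float
    method_used: str


@dataclass(frozen=True)
class CompoundSignatureScore:
    """Per-compound, per-signature p-values after instance aggregation."""

    compound_id: str
    signature_name: str
    m_instances: int
    p_pos: float
    p_neg: float


def rank_profile(
    scores: Mapping[str, float],
    instance_id: str = "instance",
    compound_id: str = "compound",
    cell_line: str = "",
) -> RankedProfile:
    """Rank a gene -> score mapping; rank 1 = largest score.

    Ties are broken deterministically by gene id, ascending.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 genes to rank")
    for g, v in scores.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite score for gene {g!r}: {v}")
    ordered = sorted(scores.items(), key=lambda gv: (-gv[1], gv[0]))
    return RankedProfile(
        instance_id=instance_id,
        compound_id=compound_id,
        cell_line=cell_line,
        n=len(ordered),
        rank_of={g: i + 1 for i, (g, _) in enumerate(ordered)},
    )


def rank_matrix(pm: ProfileMatrix) -> np.ndarray:
    """Per-column ranks of a profile matrix (1 = largest score).

    Returns an ``n x m`` int64 array; if the matrix already stores ranks it
    is returned as-is.  Ties break by gene order after a stable sort on
    descending score, which for a universe listed in ascending gene id
    matches the gene-id tie rule of :func:`rank_profile`.
    """
    if pm.is_ranks:
        return pm.values.astype(np.int64)
    n, m = pm.values.shape
    ranks = np.empty((n, m), dtype=np.int64)
    for j in range(m):
        order = np.argsort(-pm.values[:, j], kind="stable")
        ranks[order, j] = np.arange(1, n + 1)
    return ranks


def _pooled_ranks(
    sig: Signature, rank_of: Mapping[str, int], n: int, positive: bool
) -> list[int]:
    # positive match: up genes at raw ranks, down genes at reflected ranks
    raw, refl = (sig.up_genes, sig.down_genes) if positive else (
        sig.down_genes, sig.up_genes)
    pooled = [rank_of[g] for g in sorted(raw) if g in rank_of]
    pooled += [n + 1 - rank_of[g] for g in sorted(refl) if g in rank_of]
    return pooled


def _fisher_two(p_a: float, p_b: float) -> float:
    x = -2.0 * (math.log(p_a) + math.log(p_b))
    return max(float(chi2.sf(x, 4)), 5e-324)


def connectivity_score(
    sig: Signature,
    prof: RankedProfile,
    method: str = "auto",
    budget: int = DEFAULT_BUDGET,
    mode: str = "pooled",
) -> ConnectivityResult:
    """Match one signature against one ranked profile, in both directions.

    The signature should already be restricted to the profile's universe;
    genes outside it are ignored (k reduces).  An empty pooled rank list is
    an error.

    ``mode="pooled"`` (default) scores the up and down sub-signatures as one
    pooled rank product; ``mode="split_fisher"`` scores them as two separate
    rank-product tails combined with Fisher's method (reduces to a single
    tail when one side is empty).
    """
    if mode not in ("pooled", "split_fisher"):
        raise ValueError(f"unknown mode {mode!r}")
    n = prof.n
    pos = _pooled_ranks(sig, prof.rank_of, n, positive=True)
    neg = _pooled_ranks(sig, prof.rank_of, n, positive=False)
    if not pos:
        raise ValidationError(
            f"signature {sig.name!r} has no genes in instance "
            f"{prof.instance_id!r} universe"
        )
    if mode == "split_fisher":
        up_r = [prof.rank_of[g] for g in sorted(sig.up_genes)
                if g in prof.rank_of]
        down_r = [prof.rank_of[g] for g in sorted(sig.down_genes)
                  if g in prof.rank_of]

        def split_p(raw, refl):
            tails = []
            if raw:
                tails.append(rankprod_pvalue(raw, n, method, budget))
            if refl:
                tails.append(rankprod_pvalue([n + 1 - r for r in refl],
                                             n, method, budget))
            if len(tails) == 1:
                return tails[0]
            combined = _fisher_two(tails[0].pvalue, tails[1].pvalue)
            return RankProductResult(
                k=tails[0].k + tails[1].k, n=n,
                rp=tails[0].rp * tails[1].rp,
                log_stat=tails[0].log_stat + tails[1].log_stat,
                p_gamma=combined, p_exact=None, method_used="gamma",
            )

        res_pos = split_p(up_r, down_r)
        res_neg = split_p(down_r, up_r)
    else:
        res_pos = rankprod_pvalue(pos, n, method=method, budget=budget)
        res_neg = rankprod_pvalue(neg, n, method=method, budget=budget)
    k_up = sum(1 for g in sig.up_genes if g in prof.rank_of)
    k_down = sum(1 for g in sig.down_genes if g in prof.rank_of)
    return ConnectivityResult(
        signature_name=sig.name,
        instance_id=prof.instance_id,
        compound_id=prof.compound_id,
        k_up=k_up,
        k_down=k_down,
        p_pos=res_pos.pvalue,
        p_neg=res_neg.pvalue,
        method_used=res_pos.method_used,
    )


def _fisher(ps: Sequence[float]) -> float:
    x = -2.0 * sum(math.log(p) for p in ps)
    return max(float(chi2.sf(x, 2 * len(ps))), 5e-324)


def aggregate_instances(
    results: Sequence[ConnectivityResult],
    cell_lines: Sequence[str] | None = None,
) -> CompoundSignatureScore:
    """Fisher-combine instance p-values of one (compound, signature) pair.

    ``X = -2 sum ln p_i`` is chi-squared with ``2m`` degrees of freedom under
    the null; applied separately to the positive and negative directions.
    A single instance passes through unchanged (the chi2_2 tail of
    ``-2 ln p`` is exactly ``p``).

    ``cell_lines`` (one label per result, non-default) switches to
    stratified aggregation: Fisher within each cell line first, then Fisher
    across the per-cell-line combined p-values.
    """
    if not results:
        raise ValidationError("cannot aggregate an empty result list")
    compounds = {r.compound_id for r in results}
    signatures = {r.signature_name for r in results}
    if len(compounds) != 1 or len(signatures) != 1:
        raise ValidationError(
            f"aggregation mixes compounds {sorted(compounds)} / "
            f"signatures {sorted(signatures)}"
        )
    m = len(results)

    def combine(ps: list[float]) -> float:
        if cell_lines is None:
            return _fisher(ps)
        if len(cell_lines) != m:
            raise ValidationError(
                f"{len(cell_lines)} cell-line labels for {m} results"
            )
        strata: dict[str, list[float]] = {}
        for label, p in zip(cell_lines, ps):
            strata.setdefault(label, []).append(p)
        return _fisher([_fisher(v) for _, v in sorted(strata.items())])

    return CompoundSignatureScore(
        compound_id=results[0].compound_id,
        signature_name=results[0].signature_name,
        m_instances=m,
        p_pos=combine([r.p_pos for r in results]),
        p_neg=combine([r.p_neg for r in results]),
    )


def score_panel(
    panel: SignaturePanel,
    pm: ProfileMatrix,
    method: str = "auto",
    budget: int = DEFAULT_BUDGET,
) -> tuple[list[ConnectivityResult], list[CompoundSignatureScore]]:
    """Score every (signature, instance) pair and aggregate per compound.

    Vectorized over the profile matrix: columns are ranked once, signature
    genes are resolved to row indices once, and each instance contributes
    one pooled rank-product p-value per signature and direction.
    """
    ranks = rank_matrix(pm)
    n = pm.n_genes
    gene_index = {g: i for i, g in enumerate(pm.gene_universe)}
    ann = pm.annotations.set_index("instance_id")
    per_instance: list[ConnectivityResult] = []
    sig_rows = []
    for sig in panel:
        up_idx = np.array([gene_index[g] for g in sorted(sig.up_genes)
                           if g in gene_index], dtype=np.int64)
        down_idx = np.array([gene_index[g] for g in sorted(sig.down_genes)
                             if g in gene_index], dtype=np.int64)
        if up_idx.size + down_idx.size == 0:
            raise ValidationError(
                f"signature {sig.name!r} disjoint from the matrix universe"
            )
        sig_rows.append((sig, up_idx, down_idx))
    for j, inst in enumerate(pm.instances):
        col = ranks[:, j]
        compound = ann.loc[inst, "compound_id"]
        for sig, up_idx, down_idx in sig_rows:
            up_r = col[up_idx]
            down_r = col[down_idx]
            pos = np.concatenate([up_r, n + 1 - down_r])
            neg = np.concatenate([n + 1 - up_r, down_r])
            res_pos = rankprod_pvalue([int(v) for v in pos], n, method, budget)
            res_neg = rankprod_pvalue([int(v) for v in neg], n, method, budget)
            per_instance.append(ConnectivityResult(
                signature_name=sig.name,
                instance_id=inst,
                compound_id=compound,
                k_up=int(up_idx.size),
                k_down=int(down_idx.size),
                p_pos=res_pos.pvalue,
                p_neg=res_neg.pvalue,
                method_used=res_pos.method_used,
            ))
    grouped: dict[tuple[str, str], list[ConnectivityResult]] = {}
    for r in per_instance:
        grouped.setdefault((r.compound_id, r.signature_name), []).append(r)
    aggregated = [aggregate_instances(v) for _, v in sorted(grouped.items())]
    return per_instance, aggregated
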