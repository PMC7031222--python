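"""Integrate per-signature compound scores into ranked repositioning lists.

For each signature the compounds are ranked by their match p-value; a
compound's meta rank product is the product of its rank positions across
the S signatures, and its integrated p-value is the exact with-replacement
rank-product tail at the meta level (the same counting machinery used for
gene ranks, reused with n = number of compounds and k = S).  Positive and
negative lists are computed independently and BH-adjusted separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .connectivity import CompoundSignatureScore, score_panel
from .errors import ConfigError, ValidationError
from .io_formats import (
    ProfileMatrix,
    read_de_table,
    read_gmt,
    read_ortholog_map,
    read_profile_matrix,
    write_gmt,
    write_results,
)
from .rankprod import DEFAULT_BUDGET, rankprod_pvalue
from .signatures import (
    Signature,
    SignaturePanel,
    extract_signature,
    restrict_to_universe,
    translate_signature,
)

__all__ = [
    "IntegratedResult",
    "integrate_signatures",
    "bh_fdr",
    "results_to_frame",
    "run_repositioning",
    "panel_to_gmt",
]

DIRECTIONS = ("positive", "negative")


@dataclass(frozen=True)
class IntegratedResult:
    """One compound's meta rank product over the signature panel."""

    compound_id: str
    direction: str
    per_signature_ranks: tuple[int, ...]
    per_signature_ps: tuple[float, ...]
    meta_rp: int
    p_integrated: float
    q_fdr: float
    final_rank: int


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    ps = list(pvals)
    if not ps:
        return []
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
    return list(multipletests(ps, method="fdr_bh")[1])


def integrate_signatures(
    scores: Sequence[CompoundSignatureScore],
    direction: str,
    method: str = "auto",
    budget: int = DEFAULT_BUDGET,
    integration: str = "rankprod",
) -> list[IntegratedResult]:
    """Combine per-signature compound p-values into one ranked list.

    Every compound must carry a score for every signature in the panel.
    ``integration="rankprod"`` (default) uses the meta rank product with its
    exact tail; ``"fisher"`` combines the per-signature p-values directly
    with Fisher's method instead.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    sig_names = sorted({s.signature_name for s in scores})
    compounds = sorted({s.compound_id for s in scores})
    if not compounds:
        raise ValidationError("no compound scores to integrate")
    lookup: dict[tuple[str, str], float] = {}
    for s in scores:
        p = s.p_pos if direction == "positive" else s.p_neg
        lookup[(s.compound_id, s.signature_name)] = p
    for c in compounds:
        for sig in sig_names:
            if (c, sig) not in lookup:
                raise ValidationError(
                    f"incomplete panel: compound {c!r} has no score for "
                    f"signature {sig!r}"
                )
    m = len(compounds)
    S = len(sig_names)
    # per-signature compound ranks: p ascending, ties by compound id ascending
    rank_of: dict[str, list[int]] = {c: [] for c in compounds}
    for sig in sig_names:
        order = sorted(compounds, key=lambda c: (lookup[(c, sig)], c))
        for pos, c in enumerate(order, start=1):
            rank_of[c].append(pos)
    rows = []
    for c in compounds:
        rhos = rank_of[c]
        meta_rp = math.prod(rhos)
        if integration == "rankprod":
            res = rankprod_pvalue(rhos, m, method=method, budget=budget)
            p_int = res.pvalue
        elif integration == "fisher":
            x = -2.0 * sum(math.log(lookup[(c, sig)]) for sig in sig_names)
            p_int = max(float(chi2.sf(x, 2 * S)), 5e-324)
        else:
            raise ValueError(f"unknown integration {integration!r}")
        rows.append((c, tuple(rhos), meta_rp, p_int))
    rows.sort(key=lambda r: (r[3], r[2], r[0]))
    qs = bh_fdr([r[3] for r in rows])
    out = []
    for rank, ((c, rhos, meta_rp, p_int), q) in enumerate(zip(rows, qs), start=1):
        out.append(IntegratedResult(
            compound_id=c,
            direction=direction,
            per_signature_ranks=rhos,
            per_signature_ps=tuple(lookup[(c, sig)] for sig in sig_names),
            meta_rp=meta_rp,
            p_integrated=p_int,
            q_fdr=float(q),
            final_rank=rank,
        ))
    return out


def results_to_frame(
    results: Sequence[IntegratedResult], sig_names: Sequence[str]
) -> pd.DataFrame:
    """Long-form results table with one ``p:<signature>`` column per signature."""
    records = []
    for r in results:
        rec = {"compound_id": r.compound_id, "direction": r.direction}
        for sig, p in zip(sig_names, r.per_signature_ps):
            rec[f"p:{sig}"] = p
        rec.update(
            meta_rp=r.meta_rp,
            p_integrated=r.p_integrated,
            q_fdr=r.q_fdr,
            final_rank=r.final_rank,
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_repositioning(config: "RunConfig") -> dict:
    """Execute the full pipeline described by ``config``.

    extract (or load) signatures -> translate across species -> restrict to
    the matrix universe -> score every (signature, instance) pair -> Fisher
    aggregate per compound -> integrate per direction -> BH FDR.  Writes
    ``positive.tsv``, ``negative.tsv`` and ``report.txt`` plus the resolved
    config into the output directory.  Deterministic given inputs.
    """
    from .config import RunConfig  # local import to avoid cycle

    if not isinstance(config, RunConfig):
        raise ConfigError(f"expected RunConfig, got {type(config).__name__}")
    cfg = config

    # -- signatures -----------------------------------------------------
    if cfg.signatures_gmt is not None:
        panel = _read_signature_panel(cfg.signatures_gmt)
    else:
        tables = [read_de_table(p) for p in cfg.de_tables]
        panel = SignaturePanel(tuple(
            extract_signature(
                t, lfc_min=cfg.lfc_min, q_max=cfg.q_max,
                min_size=cfg.min_size, max_size=cfg.max_size,
            )
            for t in tables
        ))

    translation_notes = []
    if cfg.ortholog_map is not None:
        omap = read_ortholog_map(cfg.ortholog_map)
        translated = []
        for sig in panel:
            tsig, rep = translate_signature(sig, omap, policy=cfg.ortholog_policy)
            translated.append(tsig)
            translation_notes.append(
                f"{sig.name}: {len(rep.unmapped_genes)} unmapped, "
                f"{len(rep.conflict_genes)} direction conflicts removed"
            )
        panel = SignaturePanel(tuple(translated))

    # -- profile matrix -------------------------------------------------
    pm = read_profile_matrix(
        cfg.profile_matrix, cfg.annotations,
        dialect=cfg.matrix_dialect, values_are_ranks=cfg.values_are_ranks,
    )
    universe = frozenset(pm.gene_universe)
    restricted, k_notes = [], []
    for sig in panel:
        rsig, k_up, k_down = restrict_to_universe(sig, universe)
        restricted.append(rsig)
        k_notes.append(f"{sig.name}: k_up={k_up} k_down={k_down}")
    panel = SignaturePanel(tuple(restricted))

    # -- scoring and integration ---------------------------------------
    per_instance, aggregated = score_panel(
        panel, pm, method=cfg.method, budget=cfg.budget
    )
    sig_names = sorted(panel.names)
    outputs = {}
    for direction in DIRECTIONS:
        res = integrate_signatures(
            aggregated, direction,
            method=cfg.method, budget=cfg.budget, integration=cfg.integration,
        )
        outputs[direction] = res

    # -- outputs --------------------------------------------------------
    outdir = cfg.ensure_output_dir()
    for direction, fname in (("positive", "positive.tsv"), ("negative", "negative.tsv")):
        frame = results_to_frame(outputs[direction], sig_names)
        write_results(frame, outdir / fname)
    method_tally: dict[str, int] = {}
    for r in per_instance:
        method_tally[r.method_used] = method_tally.get(r.method_used, 0) + 1
    report_lines = [
        f"signatures (S): {len(panel)}",
        f"universe size (n): {pm.n_genes}",
        f"instances scored: {len(pm.instances)}",
        f"compounds (m): {len({r.compound_id for r in aggregated})}",
        "signature sizes after restriction:",
        *(f"  {note}" for note in k_notes),
        *(["translation:"] + [f"  {t}" for t in translation_notes]
          if translation_notes else []),
        "per-instance method tally: "
        + ", ".join(f"{k}={v}" for k, v in sorted(method_tally.items())),
    ]
    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n")
    cfg.write_resolved(outdir)
    return {
        "panel": panel,
        "per_instance": per_instance,
        "aggregated": aggregated,
        "positive": outputs["positive"],
        "negative": outputs["negative"],
        "output_dir": outdir,
    }


def _read_signature_panel(path) -> SignaturePanel:
    """Load a panel from GMT: paired ``<name>|up`` / ``<name>|down`` sets."""
    sets = read_gmt(path)
    ups: dict[str, list[str]] = {}
    downs: dict[str, list[str]] = {}
    order: list[str] = []
    for name, _desc, genes in sets:
        if name.endswith("|up"):
            base = name[:-3]
            ups[base] = genes
        elif name.endswith("|down"):
            base = name[:-5]
            downs[base] = genes
        else:
            base = name
            ups.setdefault(base, []).extend(genes)
        if base not in order:
            order.append(base)
    sigs = []
    for base in order:
        sigs.append(Signature(
            name=base,
            up_genes=frozenset(ups.get(base, ())),
            down_genes=frozenset(downs.get(base, ())),
        ))
    return SignaturePanel(tuple(sigs))


def panel_to_gmt(panel: SignaturePanel, path) -> None:
    """Write a panel as paired ``|up`` / ``|down`` GMT lines."""
    entries = []
    for sig in panel:
        entries.append((f"{sig.name}|up", sig.contrast_label or "na",
                        sorted(sig.up_genes)))
        entries.append((f"{sig.name}|down", sig.contrast_label or "na",
                        sorted(sig.down_genes)))
    write_gmt(entries, path)
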