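"""Cross-species conservation scoring of cluster marker programs.

Human variable genes are compared with each mouse cluster's DEGs after
ortholog mapping (by default the symbol case rule, mouse ``Cxcl12`` <->
human ``CXCL12``; an explicit two-column table can override it).  The
enrichment score for cluster *i* is

    ES_i = observed_i / expected_i,
    expected_i = (|MVG_human ∩ MVG_mouse| / |MVG_mouse|) * l_i,

where l_i is the number of DEGs of mouse cluster *i* and observed_i the
number of those DEGs shared with the human variable genes.  A
permutation null (drawing l_i genes uniformly from the mouse variable
genes) provides quantiles around ES = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ValidationError, logger


@dataclass
class OrthologMap:
    """Mouse symbol -> human symbol mapping (a function: one target each).

    ``source`` is ``"case_rule"`` (uppercase normalization) or
    ``"table"``; explicit table pairs override the case rule.
    """

    pairs: dict[str, str] = field(default_factory=dict)
    source: str = "case_rule"

    @classmethod
    def from_table(cls, path_or_frame) -> "OrthologMap":
        df = (
            path_or_frame
            if isinstance(path_or_frame, pd.DataFrame)
            else pd.read_csv(path_or_frame, sep="\t", header=None)
        )
        mouse = df.iloc[:, 0].astype(str)
        if mouse.duplicated().any():
            dup = sorted(mouse[mouse.duplicated()].unique())
            raise ValidationError(f"duplicate mouse symbols in ortholog table: {dup[:10]}")
        return cls(pairs=dict(zip(mouse, df.iloc[:, 1].astype(str))), source="table")

    def map_one(self, gene: str) -> str | None:
        if gene in self.pairs:
            return self.pairs[gene]
        if self.source == "case_rule" or not self.pairs:
            return gene.upper()
        return gene.upper()  # table entries override; others fall back to case rule


CASE_RULE = OrthologMap()


def map_orthologs(
    genes: Sequence[str], mapping: OrthologMap | None = None
) -> tuple[list[str], list[str]]:
    """Map mouse symbols to human; returns (mapped, unmapped-report).

    With the default case rule every symbol maps (uppercase); a table
    mapping reports genes it cannot map and drops them from the output.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("no genes to map")
    mapping = mapping or CASE_RULE
    mapped, unmapped = [], []
    for g in genes:
        if mapping.source == "table" and g not in mapping.pairs:
            unmapped.append(g)
            continue
        mapped.append(mapping.map_one(g))
    if unmapped:
        logger.info("%d genes had no ortholog and were dropped", len(unmapped))
    return mapped, unmapped


@dataclass
class EnrichmentScoreResult:
    cluster: str
    l_i: int
    observed: int
    expected: float
    es: float  # NaN when expected == 0
    shared_genes: list[str] = field(default_factory=list)


def enrichment_score(
    human_mvg: set,
    mouse_mvg: set,
    mouse_cluster_degs: Mapping[str, set],
    mapping: OrthologMap | None = None,
) -> pd.DataFrame:
    """Per-cluster observed/expected shared-gene counts and ES.

    ``human_mvg`` holds human symbols; ``mouse_mvg`` and the DEG sets
    hold mouse symbols, mapped before intersecting.  ES is NA when the
    expected count is zero (no baseline overlap) or a DEG set is empty.
    """
    human_mvg = set(map(str, human_mvg))
    mouse_mvg = set(map(str, mouse_mvg))
    if not mouse_mvg:
        raise ValidationError("empty mouse variable-gene universe")
    mapping = mapping or CASE_RULE
    mapped_universe, _ = map_orthologs(sorted(mouse_mvg), mapping)
    baseline = len(human_mvg & set(mapped_universe))
    rate = baseline / len(mouse_mvg)

    rows = []
    for cluster in sorted(mouse_cluster_degs):
        degs = set(map(str, mouse_cluster_degs[cluster]))
        outside = degs - mouse_mvg
        if outside:
            logger.warning(
                "cluster %s: %d DEGs outside the mouse variable-gene universe",
                cluster, len(outside),
            )
        if not degs:
            logger.warning("cluster %s: empty DEG set", cluster)
            rows.append(
                {"cluster": cluster, "l_i": 0, "observed": 0,
                 "expected": 0.0, "es": np.nan, "shared_genes": []}
            )
            continue
        mapped_degs, _ = map_orthologs(sorted(degs), mapping)
        shared = sorted(human_mvg & set(mapped_degs))
        l_i = len(degs)
        expected = rate * l_i
        es = len(shared) / expected if expected > 0 else np.nan
        rows.append(
            {
                "cluster": cluster,
                "l_i": l_i,
                "observed": len(shared),
                "expected": expected,
                "es": es,
                "shared_genes": shared,
            }
        )
    return pd.DataFrame(rows)


def es_permutation_ci(
    human_mvg: set,
    mouse_mvg: set,
    mouse_cluster_degs: Mapping[str, set],
    mapping: OrthologMap | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Null ES quantiles per cluster by resampling DEG sets from the universe.

    For each cluster, l_i genes are drawn uniformly without replacement
    from the mouse variable genes ``n_perm`` times; the resulting null
    ES distribution has mean 1 by construction and its 2.5% / 97.5%
    quantiles calibrate the observed score.
    """
    rng = np.random.default_rng(seed)
    obs = enrichment_score(human_mvg, mouse_mvg, mouse_cluster_degs, mapping)
    mapping = mapping or CASE_RULE
    universe = sorted(set(map(str, mouse_mvg)))
    mapped_universe, _ = map_orthologs(universe, mapping)
    hit = np.array([g in set(map(str, human_mvg)) for g in mapped_universe])
    rate = hit.mean()

    rows = []
    for _, r in obs.iterrows():
        l_i = int(r["l_i"])
        if l_i == 0 or rate == 0:
            rows.append({"cluster": r["cluster"], "es": r["es"],
                         "null_mean": np.nan, "null_q025": np.nan, "null_q975": np.nan})
            continue
        draws = np.empty(n_perm)
        expected = rate * l_i
        for j in range(n_perm):
            pick = rng.choice(len(universe), size=l_i, replace=False)
            draws[j] = hit[pick].sum() / expected
        rows.append(
            {
                "cluster": r["cluster"],
                "es": r["es"],
                "null_mean": float(draws.mean()),
                "null_q025": float(np.quantile(draws, 0.025)),
                "null_q975": float(np.quantile(draws, 0.975)),
            }
        )
    return pd.DataFrame(rows)
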