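"""End-to-end species-tree inference from a set of gene trees.

The pipeline chains: read gene trees -> normalize supports (support mode)
-> per-gene weighted path-sum tables -> average matrix -> two-stage
imputation if (and only if) the matrix is incomplete -> BME search ->
species tree.  A run report captures everything needed to reproduce the
run: configuration echo, matrix statistics, the final balanced length and
per-stage wall-clock timings.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

from . import bme_engine, matrix_completion, weighted_distance
from .bme_engine import SearchConfig
from .tree_model import (
    SupportScale,
    TaxonRegistry,
    Tree,
    normalize_supports,
    read_gene_trees,
    write_tree,
)
from .weighted_distance import EdgeWeightMode

__all__ = ["RunConfig", "RunReport", "infer_species_tree", "run_report_json"]

_MODE_ALIASES = {
    "internode": EdgeWeightMode("unweighted"),
    "support": EdgeWeightMode("support"),
    "length": EdgeWeightMode("pathlength", "max_path"),
    "length-raw": EdgeWeightMode("pathlength", "none"),
}


@dataclass
class RunConfig:
    """Serializable configuration of one inference run.

    ``mode`` is one of ``internode`` (unweighted edge counts), ``support``
    (support-weighted, the recommended default) or ``length``
    (branch-length-weighted with per-gene max-path normalization;
    ``length-raw`` disables the normalization).
    """

    mode: str = "support"
    support_scale: str = "raw01"
    missing_support: float = 1.0
    support_dialect: str = "node_label"
    imputation: str = "auto"  # auto | off
    moves: str = "nni_and_spr"
    insertion_order: str = "matrix_order"
    seed: int = 0

    def weight_mode(self) -> EdgeWeightMode:
        if self.mode not in _MODE_ALIASES:
            raise ValueError(
                f"mode must be one of {sorted(_MODE_ALIASES)}, got {self.mode!r}"
            )
        return _MODE_ALIASES[self.mode]

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            moves=self.moves,
            insertion_order=self.insertion_order,
            seed=self.seed,
        )


@dataclass
class RunReport:
    config: dict
    n_taxa: int = 0
    n_genes: int = 0
    n_missing_pairs: int = 0
    imputation_used: bool = False
    balanced_length: float = 0.0
    timings_sec: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def run_report_json(report: RunReport) -> str:
    """Machine-readable run manifest with stable key order."""
    return report.to_json()


def infer_species_tree(
    source: str | Sequence[Tree],
    config: RunConfig = RunConfig(),
    registry: Optional[TaxonRegistry] = None,
) -> tuple[Tree, RunReport]:
    """Run the full pipeline and return (species tree, run report).

    ``source`` is a newick path/text or an already-parsed list of gene
    trees (in which case ``registry`` may be supplied; otherwise it is
    rebuilt from the trees in first-appearance order).
    """
    report = RunReport(config=asdict(config))
    timings = report.timings_sec
    t0 = time.perf_counter()

    if isinstance(source, (str, bytes)):
        trees, registry = read_gene_trees(source, config.support_dialect)
    else:
        trees = list(source)
        if registry is None:
            registry = TaxonRegistry()
            for t in trees:
                for lab in t.leaf_labels():
                    registry.add(lab)
    timings["read"] = time.perf_counter() - t0
    report.n_genes = len(trees)
    report.n_taxa = len(registry)

    mode = config.weight_mode()
    t0 = time.perf_counter()
    if mode.mode == "support":
        scale = SupportScale(config.support_scale)
        trees = [
            normalize_supports(t, scale, config.missing_support) for t in trees
        ]
    timings["normalize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    avg = weighted_distance.average_matrix(trees, mode, registry)
    timings["distance"] = time.perf_counter() - t0
    report.n_missing_pairs = avg.n_missing_pairs

    search_cfg = config.search_config()
    t0 = time.perf_counter()
    if avg.is_complete:
        D = avg.D
    else:
        if config.imputation == "off":
            raise ValueError(
                f"average matrix has {avg.n_missing_pairs} missing pair(s) "
                "and imputation is off"
            )
        completion = matrix_completion.two_stage_completion(avg, search_cfg)
        D = completion.D2
        report.imputation_used = True
    timings["imputation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    scored = bme_engine.search(D, search_cfg, labels=avg.labels)
    timings["search"] = time.perf_counter() - t0
    report.balanced_length = scored.balanced_length
    return scored.to_tree(avg.labels), report
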