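"""End-to-end anchoring: preprocess -> per-chromosome optimization."""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Sequence

from .map_model import MapCollection, ScaffoldConfiguration
from .ordering import ChromosomeScorer, GAParams, order_and_orient
from .preprocess import ChromosomeProblem, PreprocessReport, preprocess

logger = logging.getLogger(__name__)

__all__ = ["anchor", "write_order_tsv", "read_order_tsv"]

_ORIENT_CHAR = {1: "+", -1: "-", 0: "?"}
_CHAR_ORIENT = {"+": 1, "-": -1, "?": 0}


def anchor(
    collection: MapCollection,
    params: GAParams | None = None,
) -> tuple[list[ScaffoldConfiguration], list[ChromosomeProblem], PreprocessReport]:
    """Run preprocessing and the two-phase optimization per chromosome.

    Chromosome sub-problems get deterministic per-chromosome seeds derived
    from ``params.seed``; the log records L before and after refinement.
    """
    params = params or GAParams()
    problems, report = preprocess(collection)
    configs: list[ScaffoldConfiguration] = []
    for i, problem in enumerate(problems):
        sub_params = GAParams(
            npop=params.npop,
            window=params.window,
            p_mut=params.p_mut,
            p_cross=params.p_cross,
            tournament=params.tournament,
            max_rounds=params.max_rounds,
            max_gen=params.max_gen,
            seed=params.seed * 100_003 + i,
        )
        config = order_and_orient(problem, sub_params)
        scorer = ChromosomeScorer(problem)
        perm = [scorer.index[sid] for sid, _ in config.entries]
        signs = [0] * len(scorer.scaffold_ids)
        for sid, o in config.entries:
            signs[scorer.index[sid]] = o
        logger.info(
            "%s: %d scaffolds, %d markers, final L = %g",
            problem.chromosome_id,
            len(problem.scaffold_ids),
            problem.n_markers,
            scorer.score(perm, signs),
        )
        configs.append(config)
    return configs, problems, report


def write_order_tsv(
    configs: Sequence[ScaffoldConfiguration], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tscaffold\torientation\n")
        for config in configs:
            for sid, orient in config.entries:
                fh.write(f"{config.chromosome_id}\t{sid}\t{_ORIENT_CHAR[orient]}\n")


def read_order_tsv(path: str | os.PathLike) -> list[ScaffoldConfiguration]:
    configs: dict[str, ScaffoldConfiguration] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chromosome\t"):
            raise ValueError(f"{path}: not an order TSV")
        for line in fh:
            chrom, sid, orient = line.rstrip("\n").split("\t")
            config = configs.setdefault(chrom, ScaffoldConfiguration(chrom, []))
            config.entries.append((sid, _CHAR_ORIENT[orient]))
    return list(configs.values())
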