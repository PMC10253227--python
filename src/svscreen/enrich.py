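"""Gene-set over-representation, direction tests, viability normalization
and whole-pipeline orchestration.

`top_n_enrichment` is the classic hypergeometric over-representation
analysis of the screen's top-ranked genes against named gene sets (with
the analyzed genes as the universe).  `direction_set_test` asks whether
a set is enriched for up-regulated genes in an externally produced
differential-expression table.  `normalize_viability` is the minimal
plate-reader operation: luminescence relative to the mean no-treatment
control.  `run_pipeline` wires simulation, screen analysis, cross-screen
comparison and enrichment into one reproducible run directory.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import hypergeom_upper, set_relative_score_test
from .exceptions import ConfigError, DataError
from .io import (
    GeneSet,
    GeneSetCollection,
    SgRNALibrary,
    read_count_table,
    read_gene_results,
    read_gene_sets,
    write_count_table,
)
from .screen import ScreenModel, bh_adjust

DEFAULT_TOP_N = 30


def top_n_enrichment(
    results: pd.DataFrame,
    sets: GeneSetCollection,
    n: int = DEFAULT_TOP_N,
) -> pd.DataFrame:
    """Over-representation of each gene set among the top-N genes by logFC.

    The universe is every gene in ``results`` (only analyzed genes can be
    selected); the top N are taken by descending logFC with ties broken
    by gene name for determinism.  Per set, ``p = P(overlap >= k)`` under
    the hypergeometric distribution, then Benjamini-Hochberg across sets.
    Rows are sorted by (p, set_name).
    """
    universe = set(results["gene"])
    if n > len(universe):
        raise ConfigError(f"top_n={n} exceeds the {len(universe)} analyzed genes")
    ordered = results.sort_values(
        ["logFC", "gene"], ascending=[False, True], kind="mergesort"
    )
    selected = set(ordered["gene"].head(n))
    rows = []
    for gs in sets:
        in_universe = gs.genes & universe
        overlap = sorted(in_universe & selected)
        k, K, N = len(overlap), len(in_universe), len(universe)
        p = 1.0 if K == 0 else hypergeom_upper(k, n, K, N)
        rows.append((gs.name, K, k, ",".join(overlap), p))
    df = pd.DataFrame(
        rows, columns=["set_name", "set_size_in_universe", "overlap",
                       "overlap_genes", "p"]
    )
    df["fdr"] = bh_adjust(df["p"]) if len(df) else pd.Series(dtype=float)
    return df.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class DirectionTest:
    """Up-direction over-representation of one set in a DE table."""

    set_name: str
    n_in_table: int
    k_up_in_set: int
    n_up_total: int
    table_size: int
    p: float


def direction_set_test(de: pd.DataFrame, gene_set: GeneSet | frozenset[str]) -> DirectionTest:
    """Are a set's members over-represented among up-regulated genes?

    Population = all genes in the DE table; successes = genes labeled
    ``up``; draws = set members present in the table.  A set absent from
    the table (or a table with no up genes) gives p = 1.
    """
    if isinstance(gene_set, GeneSet):
        name, members = gene_set.name, gene_set.genes
    else:
        name, members = "<set>", frozenset(gene_set)
    genes = de["gene"]
    if not genes.is_unique:
        raise DataError("DE table has duplicate gene rows")
    up = set(genes[de["direction"] == "up"])
    in_table = set(genes) & members
    N, K, n = len(genes), len(up), len(in_table)
    k = len(in_table & up)
    p = 1.0 if (n == 0 or K == 0) else hypergeom_upper(k, n, K, N)
    return DirectionTest(name, n, k, K, N, p)


def normalize_viability(
    readings: Sequence[float], control_readings: Sequence[float]
) -> np.ndarray:
    """Relative survival: each reading over the mean no-treatment control."""
    controls = np.asarray(control_readings, dtype=float)
    if controls.size == 0 or controls.mean() <= 0:
        raise DataError("control readings must have a positive mean")
    return np.asarray(readings, dtype=float) / controls.mean()


# ---------------------------------------------------------------------------
# pipeline orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path, log=None) -> Path:
    """Execute simulate (optional) -> analyze -> compare -> enrich.

    ``config`` keys: ``control_condition`` (required), ``pseudocount``,
    ``alpha``, ``top_n``, ``seed``, and either a ``simulate`` block of
    :class:`~svscreen.simulate.SimConfig` fields or an ``inputs`` block
    with ``counts``/``metadata``/``library`` paths; optional
    ``gene_sets`` (GMT path) and ``control_results`` (gene-results TSV
    of a control screen for the relative-rank comparison).

    Writes result TSVs, a run log and ``manifest.json`` (package
    version, parameters, seed, SHA-256 checksums of inputs and outputs)
    into ``out_dir`` and returns that path.
    """
    if log is None:
        log = sys.stderr
    if "control_condition" not in config:
        raise ConfigError("config must name a control_condition")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def say(msg: str) -> None:
        log_lines.append(msg)
        print(msg, file=log)

    seed = int(config.get("seed", 0))
    input_files: dict[str, str] = {}

    if "simulate" in config:
        from .simulate import SimConfig, simulate_screen

        sim_kwargs = dict(config["simulate"])
        sim_kwargs.setdefault("seed", seed)
        sim = SimConfig(**sim_kwargs)
        say(f"simulate: {sim.n_genes} genes x {sim.sgrnas_per_gene} guides, "
            f"depth {sim.depth}, seed {sim.seed}")
        counts, library, truth = simulate_screen(sim)
        write_count_table(counts, library,
                          out / "counts.tsv", out / "samples.tsv")
        library.to_tsv(out / "library.tsv")
        truth.to_tsv(out / "truth.tsv")
        with open(out / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(sim.to_dict(), fh, sort_keys=True)
    elif "inputs" in config:
        paths = config["inputs"]
        for key in ("counts", "metadata", "library"):
            if key not in paths:
                raise ConfigError(f"inputs block missing {key!r}")
            input_files[key] = str(paths[key])
        counts = read_count_table(paths["counts"], paths["metadata"])
        library = SgRNALibrary.from_tsv(paths["library"])
    else:
        raise ConfigError("config needs either a 'simulate' or an 'inputs' block")

    model = ScreenModel(
        counts,
        library,
        control_condition=config["control_condition"],
        pseudocount=float(config.get("pseudocount", 0.5)),
        alpha=float(config.get("alpha", 0.05)),
    )
    results = model.fit()
    say(str(results.filter_report))
    say(f"analyze: {len(results.gene_table)} genes, "
        f"{int(results.gene_table['hit'].sum())} hits")
    results.to_tsv(out / "gene_results.tsv")

    sets = None
    if config.get("gene_sets"):
        input_files["gene_sets"] = str(config["gene_sets"])
        sets = read_gene_sets(config["gene_sets"])

    if config.get("control_results"):
        input_files["control_results"] = str(config["control_results"])
        from .compare import compare_screens

        control_table = read_gene_results(config["control_results"])
        comparison = compare_screens(results.gene_table, control_table)
        comparison.to_tsv(out / "comparison.tsv")
        say(f"compare: {len(comparison.expressed)} genes in both screens")
        if sets is not None:
            rows = []
            for gs in sets:
                st = set_relative_score_test(comparison, gs)
                rows.append(
                    (st.set_name, st.n_expressed, st.n_above_1,
                     st.population, st.population_above_1, st.p,
                     ",".join(st.members_above_100))
                )
            pd.DataFrame(
                rows,
                columns=["set_name", "n_expressed", "n_above_1", "population",
                         "population_above_1", "p", "members_above_100"],
            ).to_csv(out / "set_score_tests.tsv", sep="\t", index=False,
                     float_format="%.6g")

    if sets is not None:
        top_n = int(config.get("top_n", DEFAULT_TOP_N))
        enr = top_n_enrichment(results.gene_table, sets, n=top_n)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        say(f"enrich: top {top_n} genes against {len(sets)} sets")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    manifest = {
        "svscreen_version": __version__,
        "parameters": {
            k: config[k]
            for k in ("control_condition", "pseudocount", "alpha", "top_n")
            if k in config
        },
        "seed": seed,
        "simulate": config.get("simulate"),
        "inputs": {k: _sha256(Path(v)) for k, v in input_files.items()},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.tsv"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
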