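"""Loading expression data and module definitions; writing result tables.

Expression files are delimited text with samples in rows and genes in
columns (header row of gene ids, first column sample ids); ``genes_in_rows``
transposes.  Module membership is either a two-column table
(module_id, gene_id) or a JSON object mapping module id to a gene list.
Modules may overlap; FDR adjustment is applied within each statistic across
modules.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .permutation import (
    ModuleTestResult,
    PermutationConfig,
    fdr_adjust,
    permutation_test_multi,
)
from .similarity import ExpressionMatrix
from .simulate import ScenarioSpec, simulate_group_pair
from .stats import StatisticSpec

__all__ = [
    "load_expression",
    "load_modules",
    "run_module_tests",
    "attach_fdr",
    "results_frame",
    "write_results",
    "make_fixture",
]

logger = logging.getLogger("dcmtest")

MIN_MODULE_GENES = 3


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


def load_expression(
    path: str | Path,
    genes_in_rows: bool = False,
    group_label: str = "",
) -> ExpressionMatrix:
    """Load a delimited expression file into an :class:`ExpressionMatrix`.

    Raises a descriptive error for non-numeric cells, duplicate gene ids or
    missing values (imputation is out of scope; clean the data upstream).
    """
    path = Path(path)
    df = _read_table(path)
    if not genes_in_rows:
        # pandas mangles duplicate header names (gA, gA.1); inspect the raw header
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dup_raw = sorted({g for g in header if header.count(g) > 1})
        if dup_raw:
            raise ValueError(f"{path}: duplicate gene ids {', '.join(dup_raw)}")
    else:
        df = df.T
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if df.isna().any().any():
        genes = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in genes {', '.join(map(str, genes))}")
    if len(bad):
        raise ValueError(f"{path}: non-numeric values in columns {', '.join(map(str, bad))}")
    dupes = df.columns[df.columns.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate gene ids {', '.join(map(str, dupes))}")
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(g) for g in df.columns],
        [str(s) for s in df.index],
        group_label or Path(path).stem,
    )


def load_modules(path: str | Path) -> dict[str, list[str]]:
    """Load module definitions (two-column table or JSON mapping)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        return {str(k): [str(g) for g in v] for k, v in raw.items()}
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: module file needs two columns (module_id, gene_id)")
    modules: dict[str, list[str]] = {}
    for mod, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        modules.setdefault(str(mod), []).append(str(gene))
    return modules


def run_module_tests(
    x1: ExpressionMatrix,
    x2: ExpressionMatrix,
    modules: dict[str, list[str]],
    specs: list[StatisticSpec],
    cfg: PermutationConfig,
    drop_missing_genes: bool = False,
) -> list[ModuleTestResult]:
    """Test every module with every statistic; attach FDR within statistic.

    Genes listed in a module but absent from the expression data are an
    error unless ``drop_missing_genes``; modules reduced below
    3 genes are skipped with a warning.
    """
    if x1.gene_ids != x2.gene_ids:
        raise ValueError("the two groups must share the same genes in the same order")
    available = set(x1.gene_ids)
    results: list[ModuleTestResult] = []
    for module_id, genes in modules.items():
        missing = [g for g in genes if g not in available]
        if missing:
            if not drop_missing_genes:
                raise KeyError(
                    f"module {module_id}: genes not in expression data: {', '.join(missing)}"
                )
            logger.warning("module %s: dropping %d missing genes", module_id, len(missing))
            genes = [g for g in genes if g in available]
        if len(genes) < MIN_MODULE_GENES:
            logger.warning("module %s: fewer than %d genes after filtering; skipped",
                           module_id, MIN_MODULE_GENES)
            continue
        results.extend(
            permutation_test_multi(x1.subset(genes), x2.subset(genes), specs, cfg, module_id)
        )
    return attach_fdr(results)


def attach_fdr(results: list[ModuleTestResult]) -> list[ModuleTestResult]:
    """Benjamini–Hochberg adjust p-values within each statistic across modules."""
    by_stat: dict[str, list[ModuleTestResult]] = {}
    for r in results:
        by_stat.setdefault(r.statistic_name, []).append(r)
    for group in by_stat.values():
        adjusted = fdr_adjust([r.p_value for r in group])
        for r, q in zip(group, adjusted):
            r.fdr = float(q)
    return results


def results_frame(results: list[ModuleTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module_id": [r.module_id for r in results],
            "n_genes": [r.n_genes for r in results],
            "statistic": [r.statistic_name for r in results],
            "observed": [r.observed_value for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
        }
    )


def write_results(results: list[ModuleTestResult], path: str | Path, force: bool = False) -> None:
    """Write one row per (module, statistic) as delimited text."""
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True / --force to overwrite")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    results_frame(results).to_csv(path, sep=sep, index=False)


def make_fixture(
    scenario: ScenarioSpec,
    seed: int,
    out_dir: str | Path,
    module_id: str = "module1",
) -> dict[str, Path]:
    """Write a deterministic simulated two-group dataset plus module file.

    Reloading the files reproduces the in-memory matrices exactly (full
    float precision is preserved); identical (scenario, seed) give
    byte-identical files.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    x1, x2 = simulate_group_pair(scenario, rng)
    paths = {
        "group1": out_dir / "group1.csv",
        "group2": out_dir / "group2.csv",
        "modules": out_dir / "modules.csv",
    }
    for key, x in (("group1", x1), ("group2", x2)):
        pd.DataFrame(x.values, index=x.sample_ids, columns=x.gene_ids).to_csv(
            paths[key], float_format="%.17g"
        )
    pd.DataFrame({"module": [module_id] * len(x1.gene_ids), "gene": x1.gene_ids}).to_csv(
        paths["modules"], header=False, index=False
    )
    return paths
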