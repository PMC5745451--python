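"""End-to-end study orchestration.

Stages: preprocess (duplicate-gene and duplicate-age collapsing, gene
panel restriction) -> pooled-threshold binarization with significance
filter -> group split -> per-group best-fit reconstruction -> network
sampling + perturbation protocol -> group comparison -> report files.

The group split happens strictly after binarization: one threshold per
gene is learned from all samples pooled, then the binary matrix is cut
into the young and aged series for inference.
"""

from __future__ import annotations

import json
import logging
import sys
import time
import urllib.request
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import gmean

from . import __version__
from .binarize import SCORE_VARIANT, SIGNIFICANCE_VARIANT, binarize_matrix
from .infer import FunctionSet, reconstruct
from .network import write_rules
from .stability import PerturbationConfig, StabilitySummary, compare_groups, stability_experiment

log = logging.getLogger("boolstab")

#: Entrez identifiers of the curated 22-gene NF-kB signaling panel
NFKB_PANEL_FILE = Path(__file__).parent / "data" / "nfkb_panel.tsv"

GSE362_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/GSEnnn/GSE362/matrix/GSE362_series_matrix.txt.gz"
)


@dataclass
class PipelineConfig:
    """All knobs of a study run; serialized verbatim into the manifest."""

    alpha: float = 0.05
    n_bootstrap: int = 1000
    max_k: int = 5
    expansion_cap: int = 1024
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    seed: int = 0
    group_order: tuple[str, str] = ("young", "aged")


def load_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV/CSV; first column = gene identifier."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def load_sample_sheet(path) -> pd.DataFrame:
    """Read the sample -> group/age sidecar TSV."""
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "age"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return sheet


def load_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def preprocess(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    gene_list: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse duplicates, order samples by age within group, restrict genes.

    Duplicate gene rows are collapsed by geometric mean (values must be
    strictly positive); samples sharing (group, age) are collapsed by
    arithmetic mean.  Returns the cleaned matrix (columns in time order:
    young ages ascending, then aged) and the collapsed sample sheet.
    """
    missing = set(sample_sheet["sample"]) - set(matrix.columns)
    if missing:
        raise ValueError(f"samples in sheet missing from matrix: {sorted(missing)}")
    matrix = matrix[list(sample_sheet["sample"])]

    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()].unique()
        for g in dup:
            if (matrix.loc[[g]].to_numpy() <= 0).any():
                raise ValueError(f"gene {g!r} has nonpositive values; geometric mean undefined")
        matrix = matrix.groupby(level=0, sort=False).agg(gmean)
        log.info("collapsed %d duplicate gene rows by geometric mean", len(dup))

    sheet = sample_sheet.copy()
    key = list(zip(sheet["group"], sheet["age"]))
    if len(set(key)) != len(key):
        merged_cols = {}
        records = []
        for (grp, age), sub in sheet.groupby(["group", "age"], sort=False):
            cols = list(sub["sample"])
            name = cols[0] if len(cols) == 1 else f"{grp}_{age}"
            merged_cols[name] = matrix[cols].mean(axis=1)
            records.append({"sample": name, "group": grp, "age": age})
        matrix = pd.DataFrame(merged_cols, index=matrix.index)
        sheet = pd.DataFrame(records)
        log.info("collapsed duplicate-age samples; %d samples remain", len(sheet))

    sheet["group"] = pd.Categorical(sheet["group"], categories=sheet["group"].unique())
    sheet = sheet.sort_values(["group", "age"], kind="stable").reset_index(drop=True)
    matrix = matrix[list(sheet["sample"])]

    if gene_list is not None:
        present = [g for g in gene_list if g in matrix.index]
        log.info("gene list: %d of %d identifiers found in matrix", len(present), len(gene_list))
        matrix = matrix.loc[present]
    return matrix, sheet


def split_groups(binary: pd.DataFrame, sheet: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cut a binarized matrix into per-group series (columns stay ordered)."""
    return {
        grp: binary[list(sub["sample"])]
        for grp, sub in sheet.groupby("group", sort=False, observed=True)
    }


def mean_inputs_per_function(fs: FunctionSet) -> float:
    """Mean regulator count over all candidate functions (constants count 0)."""
    return fs.mean_inputs_per_function()


def fetch_gse362(cache_dir, url: str = GSE362_URL) -> Path:
    """Download and cache the study's GEO series-matrix file (needs network)."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / "GSE362_series_matrix.txt.gz"
    if not dest.exists():
        log.info("downloading %s", url)
        urllib.request.urlretrieve(url, dest)  # noqa: S310 - fixed https URL
    return dest


@dataclass
class StudyReport:
    """In-memory results of a full run (also written to the output dir)."""

    binarization: pd.DataFrame
    retained_genes: list[str]
    function_sets: dict[str, FunctionSet]
    summaries: dict[str, StabilitySummary]
    comparison: pd.DataFrame
    manifest: dict


def _stage(name: str, t0: float, **counts) -> None:
    extra = ", ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage %-10s %6.2fs  %s", name, time.perf_counter() - t0, extra)


def run_study(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    gene_list: list[str] | None = None,
    outdir=None,
) -> StudyReport:
    """Execute every stage on an expression matrix and emit the report."""
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    matrix, sheet = preprocess(matrix, sample_sheet, gene_list)
    _stage("preprocess", t0, genes=matrix.shape[0], samples=matrix.shape[1])

    t0 = time.perf_counter()
    binary, info = binarize_matrix(matrix, cfg.alpha, cfg.n_bootstrap, seed=cfg.seed)
    dropped = int((~info["significant"]).sum())
    _stage("binarize", t0, retained=binary.shape[0], dropped=dropped)

    groups = split_groups(binary, sheet)
    function_sets: dict[str, FunctionSet] = {}
    t0 = time.perf_counter()
    for grp in cfg.group_order:
        if grp not in groups:
            raise ValueError(f"group {grp!r} absent from sample sheet")
        function_sets[grp] = reconstruct(
            groups[grp], gene_ids=list(binary.index), max_k=cfg.max_k,
            expansion_cap=cfg.expansion_cap,
        )
    _stage(
        "infer", t0,
        **{f"deps_{g}": len(fs.dependencies()) for g, fs in function_sets.items()},
    )

    summaries: dict[str, StabilitySummary] = {}
    t0 = time.perf_counter()
    for gi, grp in enumerate(cfg.group_order):
        pert = PerturbationConfig(
            n_networks=cfg.perturbation.n_networks,
            n_states=cfg.perturbation.n_states,
            n_flip_bits=cfg.perturbation.n_flip_bits,
            horizons=cfg.perturbation.horizons,
            state_classes=cfg.perturbation.state_classes,
            seed=(cfg.seed * 2 + gi) % 2**31,  # distinct deterministic stream per group
        )
        summaries[grp] = stability_experiment(function_sets[grp], pert)
    _stage("stability", t0, networks=cfg.perturbation.n_networks)

    comparison = compare_groups(*(summaries[g] for g in cfg.group_order))

    manifest = {
        "package": "boolstab",
        "version": __version__,
        "python": sys.version.split()[0],
        "config": {
            "alpha": cfg.alpha,
            "n_bootstrap": cfg.n_bootstrap,
            "max_k": cfg.max_k,
            "expansion_cap": cfg.expansion_cap,
            "seed": cfg.seed,
            "group_order": list(cfg.group_order),
            "perturbation": asdict(cfg.perturbation),
        },
        "design_variants": {
            "discontinuity_score": SCORE_VARIANT + " (stand-in)",
            "significance_test": SIGNIFICANCE_VARIANT + " (stand-in)",
        },
        "counts": {
            "genes_input": int(info.shape[0]),
            "genes_retained": int(binary.shape[0]),
            "dependencies": {g: len(fs.dependencies()) for g, fs in function_sets.items()},
            "mean_inputs_per_function": {
                g: fs.mean_inputs_per_function() for g, fs in function_sets.items()
            },
            "constant_genes": {
                g: sorted(
                    fs.gene_ids[i]
                    for i, funcs in enumerate(fs.functions)
                    if all(f.is_constant for f in funcs)
                )
                for g, fs in function_sets.items()
            },
        },
    }

    report = StudyReport(
        binarization=info,
        retained_genes=list(binary.index),
        function_sets=function_sets,
        summaries=summaries,
        comparison=comparison,
        manifest=manifest,
    )
    if outdir is not None:
        write_report(report, binary, cfg, outdir)
    return report


def write_report(report: StudyReport, binary: pd.DataFrame, cfg: PipelineConfig, outdir) -> None:
    """Write all report artifacts as TSV/JSON/rule files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.binarization.to_csv(out / "binarization.tsv", sep="\t")
    binary.to_csv(out / "binary_matrix.tsv", sep="\t")

    counts = {}
    for grp, fs in report.function_sets.items():
        write_rules(out / f"rules_{grp}.txt", fs.gene_ids, fs.functions)
        deps = sorted(fs.dependencies())
        pd.DataFrame(deps, columns=["regulator", "target"]).assign(group=grp).to_csv(
            out / f"adjacency_{grp}.tsv", sep="\t", index=False
        )
        counts[grp] = fs.function_counts()
    pd.DataFrame(counts).to_csv(out / "function_counts.tsv", sep="\t")

    table = pd.concat(
        {grp: s.summary_frame() for grp, s in report.summaries.items()}, axis=1
    )
    table.columns = ["_".join(c) for c in table.columns]
    table.to_csv(out / "stability_table.tsv", sep="\t")

    per_net = {}
    for grp, s in report.summaries.items():
        for cls in s.config.state_classes:
            for h in s.config.horizons:
                per_net[f"{grp}_{cls}_h{h}"] = s.cell(cls, h)
    pd.DataFrame(per_net).to_csv(out / "per_network_means.tsv", sep="\t", index=False)

    report.comparison.reset_index().to_json(out / "comparison.json", orient="records", indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
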