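"""End-to-end orchestration of the synthetic-data analysis pipeline.

``run_pipeline`` executes the stages in dependency order — simulate,
rank, plasticity, screen, enrichment, virtual sorting, coexistence and
phenotype support — writing every stage output under one directory
together with a JSON manifest recording the seed, a configuration hash
and the produced files.  Stages are deterministic given the seed, so a
rerun with the same configuration reproduces identical content.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from plasticitome import __version__
from plasticitome.coexistence import DEFAULT_TPM_CUTOFFS, coexist_tpm, evaluate_vsort_sc
from plasticitome.enrichment import RankedList, nes_pvalue
from plasticitome.io_formats import (
    ExpressionMatrix,
    write_calls,
    write_gene_lengths,
    write_gene_stats,
    write_mtx,
    write_table,
)
from plasticitome.immunophenotype import corpus_stats, normalize, parse_phenotype
from plasticitome.plasticity import (
    gene_stats_table,
    marker_plastic_fraction,
    merge_platforms,
    screen_polarized,
)
from plasticitome.rank_norm import rank_matrix, tpm_from_counts
from plasticitome.synthetic_data import (
    SyntheticConfig,
    generate_bulk,
    generate_marker_corpus,
    generate_singlecell,
)
from plasticitome.virtual_sorting import VirtualSortParams, virtual_sort


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run."""

    outdir: str
    seed: int
    synthetic: SyntheticConfig = None  # defaults derived from seed when omitted
    vsort: VirtualSortParams = field(default_factory=VirtualSortParams)
    tpm_cutoffs: tuple[float, ...] = DEFAULT_TPM_CUTOFFS
    gsea_permutations: int = 1000

    def __post_init__(self) -> None:
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "synthetic": asdict(self.synthetic),
                "vsort": asdict(self.vsort),
                "tpm_cutoffs": list(self.tpm_cutoffs),
                "gsea_permutations": self.gsea_permutations,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(rc: RunConfig) -> str:
    return f"# plasticitome {__version__} config={rc.config_hash()} seed={rc.seed}\n"


def _write_tsv(path: Path, df: pd.DataFrame, rc: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(rc))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6f")


def tpm_matrix(counts: ExpressionMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """Convert a count matrix to TPM, sample by sample."""
    tpm = np.column_stack(
        [
            tpm_from_counts(counts.values[:, j], lengths, counts.gene_ids)
            for j in range(counts.shape[1])
        ]
    )
    return ExpressionMatrix(
        values=tpm,
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        platform="rnaseq-tpm",
    )


def run_pipeline(rc: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written as JSON).

    A stage failure is re-raised annotated with the stage name; outputs
    of completed stages remain on disk.
    """
    out = Path(rc.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": rc.seed,
        "config_hash": rc.config_hash(),
        "stages": {},
    }
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("rank", _stage_rank),
        ("plasticity", _stage_plasticity),
        ("screen", _stage_screen),
        ("gsea", _stage_gsea),
        ("vsort", _stage_vsort),
        ("coexist", _stage_coexist),
        ("phen", _stage_phen),
    ]
    for name, fn in stages:
        try:
            outputs = fn(rc, out, state)
        except Exception as exc:
            manifest["failed_stage"] = name
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = sorted(str(p.name) for p in outputs)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(rc: RunConfig, out: Path, state: dict) -> list[Path]:
    arr, rna, lengths, truth = generate_bulk(rc.synthetic)
    sc = generate_singlecell(rc.synthetic, truth)
    corpus = generate_marker_corpus(rc.synthetic)
    state.update(arr=arr, rna=rna, lengths=lengths, truth=truth, sc=sc, corpus=corpus)
    paths = {
        "array": out / "array_signal.tsv",
        "calls": out / "array_calls.tsv",
        "counts": out / "rnaseq_counts.tsv",
        "lengths": out / "lengths.tsv",
        "mtx": out / "sc_umi.mtx",
        "genes": out / "sc_genes.txt",
        "barcodes": out / "sc_barcodes.txt",
        "truth_genes": out / "truth_gene_classes.tsv",
        "truth_states": out / "truth_sample_states.tsv",
        "corpus": out / "corpus.txt",
    }
    write_table(paths["array"], arr)
    write_calls(paths["calls"], arr)
    write_table(paths["counts"], rna)
    write_gene_lengths(paths["lengths"], lengths)
    write_mtx(paths["mtx"], paths["genes"], paths["barcodes"], sc)
    _write_tsv(paths["truth_genes"], truth.gene_table, rc)
    _write_tsv(paths["truth_states"], truth.sample_states.astype(int), rc, index=True)
    paths["corpus"].write_text("\n".join(corpus.phenotypes) + "\n")
    return list(paths.values())


def _stage_rank(rc: RunConfig, out: Path, state: dict) -> list[Path]:
    tpm = tpm_matrix(state["rna"], state["lengths"])
    ranks_a = rank_matrix(state["arr"])
    ranks_r = rank_matrix(tpm)
    state.update(tpm=tpm, ranks_a=ranks_a, ranks_r=ranks_r)
    pa, pr = out / "ranks_array.tsv", out / "ranks_rnaseq.tsv"
    _write_tsv(pa, pd.DataFrame(ranks_a.values, index=ranks_a.gene_ids, columns=ranks_a.sample_ids), rc, index=True)
    _write_tsv(pr, pd.DataFrame(ranks_r.values, index=ranks_r.gene_ids, columns=ranks_r.sample_ids), rc, index=True)
    return [pa, pr]


def _stage_plasticity(rc: RunConfig, out: Path, state: dict) -> list[Path]:
    stats_a = gene_stats_table(state["ranks_a"])
    stats_r = gene_stats_table(state["ranks_r"])
    merged, pearson = merge_platforms(stats_a, stats_r)
    state.update(stats_a=stats_a, stats_r=stats_r, merged=merged, ars_pearson=pearson)
    pa, pr = out / "stats_array.tsv", out / "stats_rnaseq.tsv"
    write_gene_stats(pa, stats_a)
    write_gene_stats(pr, stats_r)
    pj = out / "platform_concordance.json"
    pj.write_text(json.dumps({"ars_pearson": pearson, "n_shared_genes": len(merged)}, indent=2))
    return [pa, pr, pj]


def _stage_screen(rc: RunConfig, out: Path, state: dict) -> list[Path]:
    polarized = screen_polarized(state["merged"])
    state["polarized"] = polarized
    p = out / "polarized_genes.txt"
    p.write_text("\n".join(polarized) + ("\n" if polarized else ""))
    return [p]


def _stage_gsea(rc: RunConfig, out: Path, state: dict) -> list[Path]:
    ranked = RankedList.from_gene_stats(state["stats_r"])
    truth = state["truth"]
    markers = [g for g, k in truth.gene_class.items() if k in ("driver", "correlated")]
    res = nes_pvalue(
        ranked, markers, n_perm=rc.gsea_permutations, seed=rc.seed
    )
    p = out / "enrichment.json"
    p.write_text(
        json.dumps(
            {
                "gene_set": "planted driver + correlated genes",
                "es": res.es,
                "nes": res.nes,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "leading_edge_size": len(res.leading_edge),
            },
            indent=2,
        )
    )
    return [p]


def _stage_vsort(rc: RunConfig, out: Path, state: dict) -> list[Path]:
    truth = state["truth"]
    results = {}
    paths = []
    for drv in truth.driver_members:
        v = virtual_sort(drv, state["ranks_r"], rc.vsort)
        results[drv] = v
        rows = []
        for g in v.delta:
            cls = (
                "correlated"
                if g in v.correlated
                else "anticorrelated" if g in v.anticorrelated else "none"
            )
            rows.append((g, v.delta[g], v.pearson[g], v.cosine[g], cls))
        df = pd.DataFrame(rows, columns=["gene", "delta", "pearson", "cosine", "class"])
        p = out / f"vsort_{drv}.tsv"
        _write_tsv(p, df, rc)
        paths.append(p)
    state["vsort"] = results
    return paths


def _stage_coexist(rc: RunConfig, out: Path, state: dict) -> list[Path]:
    tpm = state["tpm"]
    truth = state["truth"]
    sc = state["sc"]
    rows = []
    for drv, members in truth.driver_members.items():
        t_row = tpm.row(drv)
        for cls in ("correlated", "anticorrelated"):
            for g in members[cls][:5]:  # representative pairs per driver
                for cutoff in rc.tpm_cutoffs:
                    r = coexist_tpm(t_row, tpm.row(g), cutoff, pair=(drv, g))
                    rows.append(
                        (drv, g, cls, cutoff, r.coexistence_rate, r.apa_rate)
                    )
    df = pd.DataFrame(
        rows, columns=["target", "gene", "class", "cutoff", "coexistence", "apa"]
    )
    p1 = out / "coexistence_bulk.tsv"
    _write_tsv(p1, df, rc)
    # single-cell check of the first driver's virtual-sorting output
    first = next(iter(state["vsort"]))
    ev = evaluate_vsort_sc(state["vsort"][first], sc)
    p2 = out / "sc_evaluation.json"
    p2.write_text(
        json.dumps(
            {
                "target": ev.target_gene,
                "median_pearson": ev.median_pearson,
                "median_pp_rate": ev.median_pp_rate,
                "pearson_direction_ok": ev.pearson_direction_ok,
                "pp_direction_ok": ev.pp_direction_ok,
                "n_dropped": len(ev.dropped),
            },
            indent=2,
        )
    )
    return [p1, p2]


def _stage_phen(rc: RunConfig, out: Path, state: dict) -> list[Path]:
    corpus = state["corpus"]
    normalized = [
        normalize(parse_phenotype(s), corpus.aliases) for s in corpus.phenotypes
    ]
    stats = corpus_stats(normalized)
    frac = marker_plastic_fraction(corpus.markers, corpus.merged_stats, cutoff=50)
    p = out / "phenotype_support.json"
    p.write_text(
        json.dumps(
            {
                "corpus": stats,
                "marker_plastic_fraction": {
                    "n_plastic": frac["n_plastic"],
                    "n_measured": frac["n_measured"],
                    "percent": frac["percent"],
                },
            },
            indent=2,
        )
    )
    return [p]
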