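"""Plain-text serialisation of cohorts, fits and results.

Everything round-trips through TSV / JSON / edge-list text so that runs
are inspectable and diffable; no binary formats are produced.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import SyntheticCohort
from .counts import TaxaCountTable, write_count_table
from .topics import TopicLabeling, TopicModelFit

__all__ = [
    "write_cohort",
    "write_scores",
    "save_topic_fit",
    "load_topic_fit",
    "write_dag",
    "read_dag",
    "write_json_report",
]


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort as TSVs: counts (taxa x samples), sample metadata,
    clinical records, and the ground-truth latent variables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(cohort.count_table, out / "counts.tsv")
    cohort.metadata.to_csv(out / "sample_metadata.tsv", sep="\t")
    if cohort.clinical is not None:
        cohort.clinical.to_csv(out / "clinical_records.tsv", sep="\t", index=False)
    truth = cohort.truth.samples.join(
        cohort.metadata[["subject_id"]]
    ).join(cohort.truth.subjects, on="subject_id")
    truth.to_csv(out / "truth.tsv", sep="\t")


def write_scores(scores: pd.Series, path: str | Path) -> None:
    scores.rename("dysbiosis_score").to_csv(path, sep="\t",
                                            index_label="sample_id")


def save_topic_fit(fit: TopicModelFit, labeling: TopicLabeling | None,
                   path: str | Path) -> None:
    payload = {
        "K": fit.K,
        "alpha": fit.alpha,
        "eta": fit.eta,
        "seed": fit.seed,
        "n_iterations": fit.n_iterations,
        "burn_in": fit.burn_in,
        "sample_ids": fit.sample_ids,
        "taxon_ids": fit.taxon_ids,
        "topic_word": fit.topic_word.tolist(),
        "doc_topic": fit.doc_topic.tolist(),
        "loglik_trace": fit.loglik_trace.tolist(),
        "convergence_warning": bool(fit.convergence_warning),
    }
    if labeling is not None:
        payload["labeling"] = {
            "dysbiotic_topic_index": labeling.dysbiotic_topic_index,
            "normobiotic_topic_index": labeling.normobiotic_topic_index,
            "evidence": labeling.evidence,
            "margin": labeling.margin,
        }
    Path(path).write_text(json.dumps(payload))


def load_topic_fit(path: str | Path) -> tuple[TopicModelFit, TopicLabeling | None]:
    data = json.loads(Path(path).read_text())
    fit = TopicModelFit(
        K=data["K"],
        topic_word=np.asarray(data["topic_word"]),
        doc_topic=np.asarray(data["doc_topic"]),
        alpha=data["alpha"],
        eta=data["eta"],
        seed=data["seed"],
        n_iterations=data["n_iterations"],
        burn_in=data["burn_in"],
        loglik_trace=np.asarray(data["loglik_trace"]),
        sample_ids=data["sample_ids"],
        taxon_ids=data["taxon_ids"],
        convergence_warning=data["convergence_warning"],
    )
    labeling = None
    if "labeling" in data:
        lab = data["labeling"]
        labeling = TopicLabeling(
            dysbiotic_topic_index=lab["dysbiotic_topic_index"],
            normobiotic_topic_index=lab["normobiotic_topic_index"],
            evidence={int(k): v for k, v in lab["evidence"].items()},
            margin=lab["margin"],
        )
    return fit, labeling


def write_dag(dag: nx.DiGraph, path: str | Path) -> None:
    lines = [f"{u}\t{v}" for u, v in sorted(dag.edges)]
    isolated = sorted(set(dag.nodes) - {n for e in dag.edges for n in e})
    lines += [f"{n}\t" for n in isolated]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dag(path: str | Path) -> nx.DiGraph:
    g = nx.DiGraph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) == 2 and parts[1]:
            g.add_edge(parts[0], parts[1])
        else:
            g.add_node(parts[0])
    return g


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def load_count_table_dir(path: str | Path) -> TaxaCountTable:
    from .counts import load_count_table
    return load_count_table(Path(path) / "counts.tsv")
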