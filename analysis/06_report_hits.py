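#!/usr/bin/env python
"""Threshold the fitted results at the adjusted level, classify hits by
predictor role (direct vs genetic nurture) and trait, and score them
against the simulation ground truth."""
from pathlib import Path

import pandas as pd
import yaml

from methnurture import famsim, geefit, report
from methnurture.pipeline import RunConfig

RUN = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    RunConfig.from_yaml(RUN / "config_resolved.yaml")
    table = pd.read_csv(RUN / "gee_results.tsv", sep="\t", index_col=0)
    manifest = pd.read_csv(RUN / "manifest.tsv", sep="\t")
    alpha = float(dict(
        line.split("\t") for line in (RUN / "meff.txt").read_text().splitlines()
    )["alpha"])
    truth = famsim.SimulationTruth.from_dict(
        yaml.safe_load((RUN / "truth.yaml").read_text())
    )

    terms = sorted({c.rsplit("__", 1)[0] for c in table.columns if "__" in c})
    results = geefit.GeeResultTable(
        table=table, terms=terms,
        pgs_terms=[t for t in terms if not t.startswith(("intercept", "dataset_"))],
        working="independence", n_probes=len(table),
        n_converged=int(table["converged"].sum()),
        n_nonconverged=int((~table["converged"].astype(bool)).sum()),
    )
    hits = report.classify_hits(results, alpha, manifest)
    counts = report.count_by_role_trait(hits)
    hits.to_csv(RUN / "hits.tsv", sep="\t", index=False)
    (RUN / "hit_counts.txt").write_text(report.counts_to_text(counts))
    report.chromosome_summary(hits).to_csv(
        RUN / "hits_by_chromosome.tsv", sep="\t", index=False
    )

    causal = set(truth.effect_specs[0].causal_probes)
    found = set(hits["probe_id"])
    print(report.counts_to_text(counts))
    print(f"\nground truth: {len(causal)} causal probes; "
          f"{len(causal & found)} recovered among the hits, "
          f"{len(found - causal)} hit probes are false positives")


if __name__ == "__main__":
    main()
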