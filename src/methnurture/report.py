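"""Threshold GEE results, classify significant CpGs by predictor role and
trait, and summarize hit counts.

A "hit" is one (probe, PGS predictor) pair with p below the adjusted
significance level. Offspring-PGS hits measure direct genetic effects;
maternal- and paternal-PGS hits measure indirect effects (genetic nurture).
A transcription of the published buccal-EWAS hit table (51 CpGs with their
cis-mQTL annotation) ships with the package so the counting logic can be
exercised without any data access.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .geefit import GeeResultTable

HIT_COLUMNS = [
    "probe_id", "chromosome", "position", "predictor_role", "trait", "beta", "p",
]


def load_published_hits() -> pd.DataFrame:
    """The published 51-CpG hit table (probe, location, role, trait, mQTL counts)."""
    with resources.files("methnurture.data").joinpath("published_hits.tsv").open() as fh:
        tab = pd.read_csv(fh, sep="\t")
    return tab


def classify_hits(
    results: GeeResultTable, alpha: float, manifest: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per (probe, PGS predictor) with p < alpha.

    Only the 18 PGS predictors are eligible; the intercept and dataset
    dummies are never reported. Non-converged probes are excluded upstream.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    long = results.to_long(converged_only=True)
    long = long[long["term"].isin(results.pgs_terms)]
    hits = long[long["p"] < alpha].copy()
    parts = hits["term"].str.rsplit("_", n=1, expand=True)
    if len(hits):
        hits["trait"] = parts[0]
        hits["predictor_role"] = parts[1]
    else:
        hits["trait"] = pd.Series(dtype=str)
        hits["predictor_role"] = pd.Series(dtype=str)
    if manifest is not None:
        man = manifest.set_index("probe_id")[["chromosome", "position"]]
        hits = hits.join(man, on="probe_id")
    else:
        hits["chromosome"] = pd.NA
        hits["position"] = pd.NA
    return hits[HIT_COLUMNS].reset_index(drop=True)


@dataclass
class HitCounts:
    """Counts of significant CpGs by predictor role and trait."""

    by_role_trait: pd.DataFrame  # role x trait counts
    direct: int                  # offspring-PGS hits
    indirect: int                # maternal + paternal hits
    maternal: int
    paternal: int
    total: int

    def role_share(self, role: str, trait: str) -> float:
        """Share (%) of one trait's hits among all hits for that role."""
        role_total = self.by_role_trait.loc[role].sum()
        if role_total == 0:
            return float("nan")
        return 100.0 * self.by_role_trait.loc[role, trait] / role_total

    def parental_per_trait(self) -> pd.Series:
        return self.by_role_trait.loc[["maternal", "paternal"]].sum(axis=0)

    def offspring_per_trait(self) -> pd.Series:
        return self.by_role_trait.loc["offspring"]


def count_by_role_trait(hits: pd.DataFrame) -> HitCounts:
    """Tabulate hits by (predictor role, trait); direct = offspring,
    indirect = maternal + paternal."""
    roles = ["offspring", "maternal", "paternal"]
    if len(hits):
        counts = (
            hits.groupby(["predictor_role", "trait"]).size().unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame(index=pd.Index([], name="predictor_role"))
    counts = counts.reindex(roles, fill_value=0).fillna(0).astype(int)
    counts.index.name = "predictor_role"
    maternal = int(counts.loc["maternal"].sum())
    paternal = int(counts.loc["paternal"].sum())
    direct = int(counts.loc["offspring"].sum())
    return HitCounts(
        by_role_trait=counts,
        direct=direct,
        indirect=maternal + paternal,
        maternal=maternal,
        paternal=paternal,
        total=direct + maternal + paternal,
    )


def mqtl_summary(hits: pd.DataFrame, col: str = "n_cis_mqtl") -> dict:
    """Mean/median cis-mQTLs per CpG over the CpGs that have any."""
    if col not in hits.columns:
        raise KeyError(f"hit table lacks column {col!r}")
    vals = pd.to_numeric(hits[col], errors="coerce").dropna()
    return {
        "n_cpgs_with_mqtl": int(len(vals)),
        "total_mqtls": int(vals.sum()),
        "mean_per_cpg": float(vals.mean()) if len(vals) else float("nan"),
        "median_per_cpg": float(vals.median()) if len(vals) else float("nan"),
    }


def chromosome_summary(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome hit counts (a text stand-in for a Manhattan overview)."""
    if not len(hits):
        return pd.DataFrame(columns=["chromosome", "n_hits"])
    out = hits.groupby("chromosome").size().reset_index(name="n_hits")
    return out


def counts_to_text(counts: HitCounts) -> str:
    lines = [
        f"total significant (probe, predictor) pairs: {counts.total}",
        f"direct (offspring PGS): {counts.direct}",
        f"indirect (parental PGS): {counts.indirect} "
        f"(maternal {counts.maternal}, paternal {counts.paternal})",
        "",
        counts.by_role_trait.to_string(),
    ]
    return "\n".join(lines)
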