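"""End-to-end analyses over loaded gene models.

Each ``run_*`` function mirrors one published comparison:

* intergenic  -- single-exon vs multi-exon genes (FCU/NFCU/FAU/NFAU),
  optionally splitting single-exon genes into histone / non-histone;
* intragenic  -- last exons vs upstream exons, pooled and per-gene paired,
  plus genes whose CDS lies entirely in the last exon;
* windows     -- 50-codon windows flanking the last exon-exon junction,
  optionally partitioned by ESE overlap;
* binned      -- single vs multi comparison within quartile bins of CDS
  length, ESE density or Fop;
* constraint correlation -- Spearman rho of NFCU vs NFAU overall and per
  Ka/Ks quartile.

Every function reports how many records were excluded as ineligible or
UNDEFINED, so cohort accounting stays auditable.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import comparative_stats as cstats
from . import gene_models as gm
from . import genetic_code as gcode
from . import metrics

logger = logging.getLogger(__name__)

_EXCLUDE_FLAGS = frozenset(
    {gm.FLAG_MISSING_SEQUENCE, gm.FLAG_INTERNAL_STOP, gm.FLAG_BAD_LENGTH}
)


def usable_models(
    models: Sequence[gm.TranscriptModel],
) -> tuple[list[gm.TranscriptModel], Counter]:
    """Drop transcripts whose CDS does not translate cleanly; count why."""
    casualties: Counter = Counter()
    kept = []
    for t in models:
        bad = set(t.flags) & _EXCLUDE_FLAGS
        if bad:
            casualties.update(bad)
            continue
        kept.append(t)
    if casualties:
        logger.info("excluded transcripts: %s", dict(casualties))
    return kept, casualties


def gene_metric_table(
    models: Sequence[gm.TranscriptModel],
    group_mode: str = "canonical",
) -> pd.DataFrame:
    """Per-gene metric table over representative transcripts."""
    groups = gcode.nfcu_groups(group_mode)
    aa_groups = gcode.nfau_groups()
    rows = []
    for t in models:
        rows.append(
            {
                "gene_id": t.gene_id,
                "transcript_id": t.transcript_id,
                "exon_count": t.exon_count,
                "cds_len_nt": t.cds_length_nt,
                "fcu": metrics.fcu(t.codons).value,
                "nfcu": metrics.nfcu(t.codons, groups).value,
                "fau": metrics.fau(t.peptide).value,
                "nfau": metrics.nfau(t.peptide, aa_groups).value,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["gene_class"] = np.where(
            df["exon_count"] == 1, "single-exon", "multi-exon"
        )
    return df


def run_intergenic(
    models: Sequence[gm.TranscriptModel],
    histone_ids: Iterable[str] = (),
    group_mode: str = "canonical",
) -> dict[str, pd.DataFrame]:
    """Single- vs multi-exon comparison tables for all four metrics."""
    models, casualties = usable_models(models)
    table = gene_metric_table(models, group_mode)
    if table.empty or not (table["gene_class"] == "multi-exon").any():
        raise ValueError("no multi-exon reference genes in input")
    histone_ids = set(histone_ids)
    out: dict[str, pd.DataFrame] = {}
    multi = table[table["gene_class"] == "multi-exon"]
    single = table[table["gene_class"] == "single-exon"]
    for metric in ("fcu", "nfcu", "fau", "nfau"):
        ref = multi[metric].to_numpy(dtype=float)
        ref_clean = ref[~np.isnan(ref)]
        summaries = [
            cstats.compare_to_reference(ref_clean, ref, "multi-exon")
        ]
        # reference vs itself: ratio 1, p 1 by convention
        summaries[0] = cstats.GroupSummary(
            group_label="multi-exon",
            n=summaries[0].n,
            median=summaries[0].median,
            q1=summaries[0].q1,
            q3=summaries[0].q3,
            ratio_to_reference=1.0,
            p_value=1.0,
            n_undefined_dropped=summaries[0].n_undefined_dropped,
        )
        comparisons = [("single-exon:all", single)]
        if histone_ids:
            comparisons.append(
                (
                    "single-exon:non-histone",
                    single[~single["gene_id"].isin(histone_ids)],
                )
            )
            comparisons.append(
                (
                    "single-exon:histone",
                    single[single["gene_id"].isin(histone_ids)],
                )
            )
        for label, sub in comparisons:
            vals = sub[metric].to_numpy(dtype=float)
            if np.sum(~np.isnan(vals)) == 0:
                logger.warning("group %s empty for %s", label, metric)
                continue
            summaries.append(
                cstats.compare_to_reference(ref_clean, vals, label)
            )
        out[metric] = cstats.summaries_frame(summaries)
    out["exclusions"] = pd.DataFrame(
        [{"reason": k, "n": v} for k, v in sorted(casualties.items())]
        or [{"reason": "none", "n": 0}]
    )
    return out


def _intragenic_eligible(
    models: Sequence[gm.TranscriptModel],
) -> tuple[list[gm.TranscriptModel], Counter]:
    casualties: Counter = Counter()
    kept = []
    for t in models:
        if t.exon_count < 2:
            casualties["single_exon"] += 1
            continue
        if not gm.is_reliable_last_exon(t):
            casualties[gm.REASON_UNRELIABLE] += 1
            continue
        coding = t.coding_exon_indices()
        if len(coding) < 2:
            casualties["no_upstream_coding_exon"] += 1
            continue
        kept.append(t)
    return kept, casualties


def run_intragenic(
    models: Sequence[gm.TranscriptModel],
    group_mode: str = "canonical",
) -> dict[str, object]:
    """Last-exon vs upstream-exon NFCU: pooled, paired and CDS-in-last-exon."""
    models, casualties = usable_models(models)
    groups = gcode.nfcu_groups(group_mode)
    eligible, reasons = _intragenic_eligible(models)
    casualties.update(reasons)

    records: list[tuple[str, float]] = []
    paired_diffs: list[float] = []
    paired_last: list[float] = []
    paired_upstream: list[float] = []
    n_lower = n_higher = 0
    for t in eligible:
        per_exon = gm.assign_codons_to_exons(t)
        upstream_codons: list[str] = []
        last_value = None
        for ec in per_exon:
            if not ec.codons.codons:
                continue
            value = metrics.nfcu(ec.codons, groups).value
            label = "last_exon" if ec.is_last else "upstream_exon"
            records.append((label, value if value is not None else np.nan))
            if ec.is_last:
                last_value = value
            else:
                upstream_codons.extend(ec.codons.codons)
        up_value = (
            metrics.nfcu(
                metrics.CodonSequence(tuple(upstream_codons)), groups
            ).value
            if upstream_codons
            else None
        )
        if last_value is not None and up_value is not None:
            diff = last_value - up_value
            paired_diffs.append(diff)
            paired_last.append(last_value)
            paired_upstream.append(up_value)
            if diff < 0:
                n_lower += 1
            elif diff > 0:
                n_higher += 1

    summaries = cstats.summarize_groups(records, "upstream_exon")
    diffs = np.array(paired_diffs)
    last_vals = np.array(paired_last)
    up_vals = np.array(paired_upstream)
    med_last = float(np.median(last_vals)) if len(last_vals) else np.nan
    med_up = float(np.median(up_vals)) if len(up_vals) else np.nan
    paired = {
        "median_last": med_last,
        "median_upstream": med_up,
        "gene_level_ratio": med_last / med_up if med_up else np.nan,
        "n_pairs": len(diffs),
        "n_differing": int(n_lower + n_higher),
        "n_lower_in_last": int(n_lower),
        "n_higher_in_last": int(n_higher),
        "sign_test_p": cstats.sign_test(diffs) if len(diffs) else 1.0,
        "signed_rank_p": (
            cstats.signed_rank_test(diffs) if len(diffs) else 1.0
        ),
        "median_paired_difference": (
            float(np.median(diffs)) if len(diffs) else np.nan
        ),
    }

    # genes whose CDS lies entirely in the last exon vs >=2 coding exons
    cds_last_records: list[tuple[str, float]] = []
    for t in models:
        if t.exon_count < 2:
            continue
        label = (
            "cds_in_last_exon"
            if gm.cds_in_last_exon(t)
            else "multi_coding_exon"
        )
        value = metrics.nfcu(t.codons, groups).value
        cds_last_records.append(
            (label, value if value is not None else np.nan)
        )
    have_both = {label for label, _ in cds_last_records} >= {
        "cds_in_last_exon",
        "multi_coding_exon",
    }
    cds_last = (
        cstats.summaries_frame(
            cstats.summarize_groups(cds_last_records, "multi_coding_exon")
        )
        if have_both
        else pd.DataFrame()
    )
    return {
        "exon_summaries": cstats.summaries_frame(summaries),
        "paired": paired,
        "cds_in_last_exon": cds_last,
        "exclusions": pd.DataFrame(
            [{"reason": k, "n": v} for k, v in sorted(casualties.items())]
            or [{"reason": "none", "n": 0}]
        ),
    }


def run_windows(
    models: Sequence[gm.TranscriptModel],
    window_size: int = 50,
    buffer_nt: int = 50,
    hexamers: Iterable[str] | None = None,
    group_mode: str = "canonical",
) -> dict[str, object]:
    """NFCU in 5' (NMD-competent) vs 3' (NMD-compromised) windows."""
    models, casualties = usable_models(models)
    groups = gcode.nfcu_groups(group_mode)
    hexset = frozenset(hexamers) if hexamers else None
    records: list[tuple[str, float]] = []
    ese_records: dict[str, list[tuple[str, float]]] = {
        "overlapping": [],
        "external": [],
    }
    n_eligible = 0
    for t in models:
        windows, reason = gm.extract_boundary_windows(
            t, window_size=window_size, buffer_nt=buffer_nt
        )
        if windows is None:
            casualties[reason] += 1
            continue
        n_eligible += 1
        cds = "".join(t.codons.codons)
        for label, win in (
            ("five_prime", windows.five_prime_window),
            ("three_prime", windows.three_prime_window),
        ):
            value = metrics.nfcu(win, groups).value
            records.append((label, value if value is not None else np.nan))
            if hexset:
                over, ext = gm.partition_codons_by_ese(win, hexset, cds)
                for part, seq in (("overlapping", over), ("external", ext)):
                    v = metrics.nfcu(seq, groups).value
                    ese_records[part].append(
                        (label, v if v is not None else np.nan)
                    )
    if not records:
        logger.warning("no window-eligible genes")
        return {
            "summaries": pd.DataFrame(),
            "n_eligible": 0,
            "exclusions": pd.DataFrame(
                [{"reason": k, "n": v} for k, v in sorted(casualties.items())]
            ),
        }
    out: dict[str, object] = {
        "summaries": cstats.summaries_frame(
            cstats.summarize_groups(records, "five_prime")
        ),
        "n_eligible": n_eligible,
        "exclusions": pd.DataFrame(
            [{"reason": k, "n": v} for k, v in sorted(casualties.items())]
            or [{"reason": "none", "n": 0}]
        ),
    }
    if hexset:
        for part, recs in ese_records.items():
            defined = [r for r in recs if not np.isnan(r[1])]
            if {label for label, _ in defined} >= {"five_prime", "three_prime"}:
                out[f"ese_{part}"] = cstats.summaries_frame(
                    cstats.summarize_groups(recs, "five_prime")
                )
    return out


def run_binned(
    models: Sequence[gm.TranscriptModel],
    bin_variable: str = "cds_length",
    hexamers: Iterable[str] | None = None,
    optimal_codons: Iterable[str] | None = None,
    group_mode: str = "canonical",
    k: int = 4,
) -> pd.DataFrame:
    """Single vs multi NFCU within quartile bins of a pooled variable."""
    models, _ = usable_models(models)
    table = gene_metric_table(models, group_mode)
    if bin_variable == "cds_length":
        variable = table["cds_len_nt"].to_numpy(dtype=float)
    elif bin_variable == "ese_density":
        if hexamers is None:
            raise ValueError("ese_density binning requires a hexamer set")
        variable = np.array(
            [
                gm.ese_density("".join(t.codons.codons), hexamers)
                for t in models
            ]
        )
    elif bin_variable == "fop":
        if optimal_codons is None:
            raise ValueError("fop binning requires an optimal codon set")
        vals = [
            gm.fop(t.codons, optimal_codons, mode="raw").value for t in models
        ]
        variable = np.array(
            [v if v is not None else np.nan for v in vals], dtype=float
        )
        keep = ~np.isnan(variable)
        table = table[keep].reset_index(drop=True)
        variable = variable[keep]
    else:
        raise ValueError(f"unknown bin variable: {bin_variable!r}")
    assignment = cstats.quartile_bin(variable, k=k)
    table = table.assign(bin=list(assignment.labels))
    rows = []
    for bin_label in sorted(set(assignment.labels)):
        sub = table[table["bin"] == bin_label]
        multi = sub.loc[sub["gene_class"] == "multi-exon", "nfcu"].dropna()
        single = sub.loc[sub["gene_class"] == "single-exon", "nfcu"].dropna()
        row = {
            "bin": bin_label,
            "n_multi": len(multi),
            "n_single": len(single),
            "median_multi": multi.median() if len(multi) else np.nan,
            "median_single": single.median() if len(single) else np.nan,
        }
        if len(multi) and len(single):
            row["ratio"] = (
                row["median_single"] / row["median_multi"]
                if row["median_multi"]
                else np.nan
            )
            row["p_value"] = cstats.rank_sum_test(single, multi)
        else:
            row["ratio"] = np.nan
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_constraint_correlation(
    metric_table: pd.DataFrame,
    kaks: pd.DataFrame,
    k: int = 4,
) -> pd.DataFrame:
    """Spearman rho of NFCU vs NFAU, overall and per Ka/Ks quartile."""
    merged = metric_table.merge(
        kaks[["gene_id", "ratio"]], on="gene_id", how="inner"
    ).dropna(subset=["nfcu", "nfau", "ratio"])
    if merged.empty:
        raise ValueError("no genes with both metrics and Ka/Ks")
    rows = []
    overall = cstats.spearman_ci(
        merged["nfcu"], merged["nfau"], bin_label="all"
    )
    rows.append(overall)
    assignment = cstats.quartile_bin(
        merged["ratio"].to_numpy(dtype=float), k=k
    )
    merged = merged.assign(bin=list(assignment.labels))
    for bin_label in sorted(merged["bin"].unique()):
        sub = merged[merged["bin"] == bin_label]
        if len(sub) < 4:
            logger.warning("bin %s has <4 genes; skipped", bin_label)
            continue
        cb = cstats.spearman_ci(sub["nfcu"], sub["nfau"], bin_label=bin_label)
        rows.append(cb)
    frame = pd.DataFrame(
        {
            "bin": [r.bin_label for r in rows],
            "n": [r.n for r in rows],
            "rho": [r.rho for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
    mean_kaks = [
        merged.loc[merged["bin"] == b, "ratio"].mean()
        if b != "all"
        else merged["ratio"].mean()
        for b in frame["bin"]
    ]
    frame["mean_kaks"] = mean_kaks
    return frame


def write_tables(results: dict[str, object], out_dir, prefix: str = "") -> None:
    """Write every DataFrame in ``results`` as TSV; dicts go to JSON."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        stem = f"{prefix}{name}"
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
        elif isinstance(obj, dict):
            with open(out_dir / f"{stem}.json", "w") as fh:
                json.dump(obj, fh, indent=2, default=float)
        else:
            with open(out_dir / f"{stem}.json", "w") as fh:
                json.dump(obj, fh, indent=2, default=float)
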