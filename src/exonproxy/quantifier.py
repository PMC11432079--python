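"""Counting, TPM normalization, isoform fractions, and proxy validation.

Two quantification currencies are supported, matching the two library
chemistries the proxy approach serves:

* **Tag/UMI libraries** (10X-style): one placement per captured molecule.
  Molar isoform fractions come from the raw proxy-count share, optionally
  corrected for 3'-capture probability (the chance that a molecule's single
  read lands inside the proxy at all, which shrinks when the proxy is short
  relative to the library's 3'-bias scale).
* **Bulk libraries**: fragments per molecule scale with transcript length,
  so counts are first converted to TPM (count / feature length, rescaled to
  one million per sample); isoform fractions are then TPM shares.

All tables are pandas DataFrames with features as rows and samples (or
cells) as columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genomic_model import Placement
from .proxy_finder import IsoformGroup, ProxyRegion

logger = logging.getLogger(__name__)


class RegionOverlapError(ValueError):
    """Counting requires pairwise-disjoint regions."""


@dataclass
class CountPolicy:
    """featureCounts-like defaults: a placement counts for a region when any
    of its blocks overlaps the region by at least ``min_overlap`` bases; a
    placement is counted at most once per region set, and one touching two
    regions is dropped (and tallied) rather than double-counted."""

    min_overlap: int = 1
    stranded: bool = False


def _check_disjoint(regions: Sequence[ProxyRegion]) -> None:
    ivs = [(iv, r.group_name) for r in regions for iv in r.intervals]
    by_seq: dict[str, list] = {}
    for iv, name in ivs:
        by_seq.setdefault(iv.seqname, []).append((iv, name))
    for seq_ivs in by_seq.values():
        seq_ivs.sort(key=lambda t: t[0].start)
        for (a, an), (b, bn) in zip(seq_ivs, seq_ivs[1:]):
            if b.start <= a.end:
                raise RegionOverlapError(
                    f"regions {an!r} and {bn!r} overlap at {a.seqname}:{b.start}"
                )


def count_overlaps(
    placements: Iterable[Placement],
    regions: Sequence[ProxyRegion],
    policy: CountPolicy = CountPolicy(),
) -> pd.DataFrame:
    """Count placements per proxy region per sample.

    Returns an integer DataFrame (region group names x samples). Placements
    overlapping no region are ignored; those overlapping more than one are
    dropped and logged.
    """
    _check_disjoint(regions)
    counts: dict[str, dict[str, int]] = {r.group_name: {} for r in regions}
    dropped_ambiguous = 0
    samples: list[str] = []
    seen_samples: set[str] = set()

    region_ivs = [(r.group_name, list(r.intervals)) for r in regions]
    for p in placements:
        if p.sample not in seen_samples:
            seen_samples.add(p.sample)
            samples.append(p.sample)
        hits = []
        for name, ivs in region_ivs:
            hit = False
            for block in p.blocks:
                for iv in ivs:
                    if policy.stranded and iv.strand != block.strand:
                        continue
                    if block.overlap_length(iv) >= policy.min_overlap:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                hits.append(name)
        if len(hits) == 1:
            row = counts[hits[0]]
            row[p.sample] = row.get(p.sample, 0) + 1
        elif len(hits) > 1:
            dropped_ambiguous += 1
    if dropped_ambiguous:
        logger.warning("%d placements overlapped multiple regions and were dropped",
                       dropped_ambiguous)
    df = pd.DataFrame(
        {s: {r.group_name: counts[r.group_name].get(s, 0) for r in regions} for s in samples},
        dtype=int,
    )
    if df.empty:
        df = pd.DataFrame(index=[r.group_name for r in regions], dtype=int)
    return df.reindex([r.group_name for r in regions])


def tpm(counts: pd.DataFrame, lengths: Mapping[str, float]) -> pd.DataFrame:
    """Transcripts-per-million over the features present in the table.

    ``rate_i = count_i / length_i``; ``TPM_i = 1e6 * rate_i / sum_j rate_j``.
    Columns with zero total count become all-NA. The denominator is the
    supplied table, not the whole genome — proxy-only tables therefore live
    on their own TPM scale.
    """
    missing = [f for f in counts.index if f not in lengths]
    if missing:
        raise KeyError(f"no length for feature(s): {', '.join(map(str, missing))}")
    lens = pd.Series({f: float(lengths[f]) for f in counts.index})
    bad = lens[lens <= 0]
    if not bad.empty:
        raise ValueError(f"non-positive length for feature(s): {', '.join(bad.index)}")
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    rate = counts.div(lens, axis=0)
    total = rate.sum(axis=0)
    out = rate.mul(1e6).div(total, axis=1)
    out.loc[:, total == 0] = np.nan
    return out


def sum_group_tpm(
    transcript_tpm: pd.DataFrame, groups: Sequence[IsoformGroup]
) -> pd.DataFrame:
    """Sum transcript-level TPM into one row per isoform group.

    Members missing from the table contribute zero, with a warning.
    """
    rows = {}
    for g in groups:
        present = [t for t in sorted(g.transcript_ids) if t in transcript_tpm.index]
        absent = sorted(set(g.transcript_ids) - set(present))
        if absent:
            logger.warning(
                "group %s: transcripts absent from TPM table treated as 0: %s",
                g.name,
                ", ".join(absent),
            )
        rows[g.name] = (
            transcript_tpm.loc[present].sum(axis=0)
            if present
            else pd.Series(0.0, index=transcript_tpm.columns)
        )
    return pd.DataFrame(rows).T.reindex([g.name for g in groups])


def isoform_fraction(group_tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-sample simplex of group shares; all-NA where the total is zero."""
    if len(group_tpm.index) < 2:
        raise ValueError("isoform fractions need at least two groups")
    total = group_tpm.sum(axis=0)
    frac = group_tpm.div(total, axis=1)
    zero = total == 0
    if zero.any():
        logger.warning(
            "samples with zero total signal flagged NA: %s",
            ", ".join(map(str, total.index[zero])),
        )
        frac.loc[:, zero] = np.nan
    return frac


def three_prime_capture_probability(
    proxy_length: float, spliced_length: float, bias_scale: float, read_length: int = 91
) -> float:
    """Probability that a 3'-biased read overlaps a 3'-terminal proxy.

    Under the truncated-exponential bias model the read's 3'-end distance x
    from the transcript 3' end follows Exp(bias_scale) truncated to
    [0, L - read_length]; the read overlaps the terminal ``proxy_length``
    bases iff x < proxy_length.
    """
    span = max(spliced_length - read_length, 1.0)
    z = 1.0 - math.exp(-span / bias_scale)
    p = (1.0 - math.exp(-min(proxy_length, span) / bias_scale)) / z
    return min(p, 1.0)


def isoform_fraction_from_counts(
    counts: pd.DataFrame,
    capture_probability: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Molar isoform fractions for UMI/tag data: raw count shares, optionally
    dividing each group's counts by its 3'-capture probability first."""
    adj = counts.astype(float)
    if capture_probability is not None:
        probs = pd.Series({f: capture_probability[f] for f in counts.index})
        if (probs <= 0).any():
            raise ValueError("capture probabilities must be positive")
        adj = adj.div(probs, axis=0)
    return isoform_fraction(adj)


@dataclass
class AgreementReport:
    """Proxy-vs-transcript fraction comparison for matched samples."""

    per_sample: pd.Series  # mean |difference| over groups, per sample
    max_abs_diff: float
    mean_abs_diff: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return bool(self.mean_abs_diff <= self.tolerance)

    def to_dict(self) -> dict:
        return {
            "per_sample": {str(k): float(v) for k, v in self.per_sample.items()},
            "max_abs_diff": self.max_abs_diff,
            "mean_abs_diff": self.mean_abs_diff,
            "tolerance": self.tolerance,
            "passed": self.passed,
        }


def proxy_agreement(
    frac_proxy: pd.DataFrame, frac_transcript: pd.DataFrame, tolerance: float = 0.02
) -> AgreementReport:
    """Absolute per-sample difference between two fraction tables.

    Rows (groups) and columns (samples) must match up to order.
    """
    if set(frac_proxy.columns) != set(frac_transcript.columns):
        raise ValueError(
            f"sample mismatch: {sorted(frac_proxy.columns)} vs "
            f"{sorted(frac_transcript.columns)}"
        )
    if set(frac_proxy.index) != set(frac_transcript.index):
        raise ValueError(
            f"group mismatch: {sorted(frac_proxy.index)} vs "
            f"{sorted(frac_transcript.index)}"
        )
    b = frac_transcript.reindex(index=frac_proxy.index, columns=frac_proxy.columns)
    diff = (frac_proxy - b).abs()
    per_sample = diff.mean(axis=0)
    return AgreementReport(
        per_sample=per_sample,
        max_abs_diff=float(diff.max().max()),
        mean_abs_diff=float(per_sample.mean()),
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# TSV I/O (StringTie-like transcript TPM tables and our own outputs)
# ---------------------------------------------------------------------------


def read_table(path) -> pd.DataFrame:
    """Read a feature x sample TSV; first column is the feature id;
    '#'-prefixed lines are comments."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df


def write_table(df: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    with open(path, "w", newline="\n") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index_label="feature", lineterminator="\n")
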