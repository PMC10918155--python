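"""Readers, writers, run configuration and fixture generation.

All tabular interchange is TSV.  Coordinates are 1-based inclusive, matching
common copy-number-caller exports; chromosome names are accepted with or
without a ``chr`` prefix and normalized to the bare name internally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_em import SSNVTable
from .histories import CNConfig

logger = logging.getLogger("gaintimer")

__all__ = [
    "RunConfig",
    "Segment",
    "read_segments",
    "read_ssnvs",
    "read_purity",
    "assign_ssnvs_to_segments",
    "write_timing_table",
    "make_fixture",
    "FIXTURE_SCENARIOS",
]

SEGMENT_COLUMNS = ["chrom", "start", "end", "major_cn", "minor_cn"]
SSNV_COLUMNS = ["chrom", "pos", "ref", "alt", "t_alt_count", "t_depth"]
TIMING_COLUMNS = [
    "segment_id", "chrom", "start", "end", "nt", "nb", "n_ssnv",
    "t0_upper", "t0_ci_low", "t0_ci_high",
    "tK_upper", "tK_ci_low", "tK_ci_high",
    "arrival_time", "label",
]


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings (mirrors the CLI flags and the optional
    ``key = value`` config file)."""

    min_ssnv: int = 10
    max_cn: int = 7
    bootstrap: int = 200
    late_early_threshold: float = 0.2
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.late_early_threshold < 1.0):
            raise ValueError("late/early threshold must be in (0, 1)")
        if self.bootstrap < 0:
            raise ValueError("bootstrap count must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        values: dict = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}:{ln}: unknown setting {key!r}")
            if key == "log_level":
                values[key] = val
            elif key in ("late_early_threshold",):
                values[key] = float(val)
            else:
                values[key] = int(val)
        values.update(overrides)
        return cls(**values)


@dataclass(frozen=True)
class Segment:
    segment_id: str
    chrom: str
    start: int
    end: int
    cn: CNConfig


def _norm_chrom(name) -> str:
    s = str(name)
    return s[3:] if s.lower().startswith("chr") else s


def read_segments(path: str | Path) -> list[Segment]:
    """Read clonal SCNA segments from TSV (chrom, start, end, major_cn,
    minor_cn; 1-based inclusive).  Validates sorting and non-overlap per
    chromosome; errors carry the offending line number."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    segments: list[Segment] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            start, end = int(rec.start), int(rec.end)
            major, minor = int(rec.major_cn), int(rec.minor_cn)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line}: malformed row ({exc})") from exc
        if start < 1 or end < start:
            raise ValueError(f"{path}:{line}: invalid interval {start}-{end}")
        if major < minor:
            raise ValueError(
                f"{path}:{line}: major_cn {major} < minor_cn {minor}"
            )
        chrom = _norm_chrom(rec.chrom)
        segments.append(
            Segment(
                segment_id=f"{chrom}:{start}-{end}",
                chrom=chrom,
                start=start,
                end=end,
                cn=CNConfig(nt=major + minor, nb=minor),
            )
        )
    segments.sort(key=lambda s: (s.chrom, s.start))
    last: dict[str, int] = {}
    for seg in segments:
        if seg.chrom in last and seg.start <= last[seg.chrom]:
            raise ValueError(f"{path}: overlapping segments on chromosome {seg.chrom}")
        last[seg.chrom] = seg.end
    return segments


def read_ssnvs(path: str | Path, format: str = "tsv", sample: str | None = None) -> SSNVTable:
    """Read detected SSNVs with read counts from TSV or VCF.

    TSV needs columns chrom, pos, ref, alt, t_alt_count, t_depth.  VCF needs
    per-sample allele depths (FORMAT/AD); ``sample`` selects the tumor sample
    column (default: first).  Records with zero mutant reads are dropped with
    a logged warning — undetected variants carry no timing information.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(SSNV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        chrom = df["chrom"].map(_norm_chrom).to_numpy()
        pos = df["pos"].to_numpy(dtype=np.int64)
        m = df["t_alt_count"].to_numpy(dtype=np.int64)
        d = df["t_depth"].to_numpy(dtype=np.int64)
    elif format == "vcf":
        chrom, pos, m, d = _read_vcf(path, sample)
    else:
        raise ValueError(f"unknown SSNV format {format!r}")

    detected = m >= 1
    n_dropped = int((~detected).sum())
    if n_dropped:
        logger.warning("dropped %d undetected SSNVs (zero mutant reads) from %s",
                       n_dropped, path)
    return SSNVTable(chrom=chrom[detected], pos=pos[detected],
                     m=m[detected], d=d[detected])


def _read_vcf(path, sample):
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    if not vcf.samples:
        raise ValueError(f"{path}: VCF has no sample columns with depths")
    sidx = vcf.samples.index(sample) if sample else 0
    chrom, pos, m, d = [], [], [], []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"{path}: VCF record lacks the FORMAT/AD depth field")
        ref_d, alt_d = int(ad[sidx][0]), int(ad[sidx][1])
        chrom.append(_norm_chrom(var.CHROM))
        pos.append(var.POS)
        m.append(alt_d)
        d.append(ref_d + alt_d)
    return (np.array(chrom), np.array(pos, dtype=np.int64),
            np.array(m, dtype=np.int64), np.array(d, dtype=np.int64))


def read_purity(path: str | Path) -> float:
    """Read a purity scalar from a one-value text file."""
    value = float(Path(path).read_text().split()[0])
    if not (0.0 < value <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {value}")
    return value


def assign_ssnvs_to_segments(
    ssnvs: SSNVTable, segments: list[Segment]
) -> dict[str, SSNVTable]:
    """Map SSNVs to segments by inclusive coordinate containment.

    Returns {segment_id: SSNVTable}; unassigned SSNVs are counted and logged.
    """
    out: dict[str, SSNVTable] = {}
    assigned = np.zeros(len(ssnvs), dtype=bool)
    for seg in segments:
        mask = (
            (ssnvs.chrom == seg.chrom)
            & (ssnvs.pos >= seg.start)
            & (ssnvs.pos <= seg.end)
        )
        assigned |= mask
        out[seg.segment_id] = ssnvs.subset(mask)
    n_un = int((~assigned).sum())
    if n_un:
        logger.info("%d of %d SSNVs fall outside all segments", n_un, len(ssnvs))
    return out


def write_timing_table(estimates, path: str | Path, threshold: float = 0.2) -> pd.DataFrame:
    """Write per-segment timing estimates to the output TSV."""
    from .timing import classify_gain

    rows = []
    for est, seg in estimates:
        t0_ci = est.t0_ci or (float("nan"), float("nan"))
        tK_ci = est.tK_ci or (float("nan"), float("nan"))
        rows.append({
            "segment_id": est.segment_id,
            "chrom": seg.chrom, "start": seg.start, "end": seg.end,
            "nt": est.cn.nt, "nb": est.cn.nb, "n_ssnv": est.n_ssnv,
            "t0_upper": est.t0_upper, "t0_ci_low": t0_ci[0], "t0_ci_high": t0_ci[1],
            "tK_upper": est.tK_upper, "tK_ci_low": tK_ci[0], "tK_ci_high": tK_ci[1],
            "arrival_time": est.arrival,
            "label": classify_gain(est, threshold),
        })
    df = pd.DataFrame(rows, columns=TIMING_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

FIXTURE_SCENARIOS = (
    "single_gain_early",
    "single_gain_late",
    "gd_mid_with_post_gains",
    "amplified_loh",
    "cohort_recurrence",
)


def _fixture_segment_rows(specs):
    rows, truth = [], []
    pos = 1_000_000
    for (major, minor, t, label) in specs:
        length = 20_000_000
        rows.append({"chrom": "1", "start": pos, "end": pos + length - 1,
                     "major_cn": major, "minor_cn": minor})
        truth.append({"chrom": "1", "start": pos, "end": pos + length - 1,
                      "nt": major + minor, "nb": minor,
                      "t_true": list(map(float, t)), "label": label})
        pos += length + 5_000_000
    return rows, truth


def make_fixture(scenario: str, seed: int, out_dir: str | Path,
                 M: int = 300, depth: float = 150.0, purity: float = 0.9) -> Path:
    """Write a deterministic toy dataset with recorded ground truth.

    Produces ``segments.tsv``, ``ssnvs.tsv``, ``purity.txt`` and
    ``truth.json`` under ``out_dir`` (``cohort_recurrence`` instead writes
    per-patient timing tables and a ``manifest.tsv``).
    """
    from .benchmark import SimConfig, simulate_ssnvs
    from .histories import TimeFractions, enumerate_histories

    if scenario not in FIXTURE_SCENARIOS:
        raise ValueError(f"unknown fixture scenario {scenario!r}; "
                         f"choose one of {FIXTURE_SCENARIOS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if scenario == "cohort_recurrence":
        return _make_cohort_fixture(out, rng)

    if scenario == "single_gain_early":
        specs = [(2, 1, (0.1, 0.9), "early")]
    elif scenario == "single_gain_late":
        specs = [(2, 1, (0.9, 0.1), "late")]
    elif scenario == "amplified_loh":
        specs = [(4, 0, (0.4, 0.2, 0.2, 0.2), "intermediate")]
    else:  # gd_mid_with_post_gains: a burst of 5:1-like gains arriving
        # together mid-way plus later post-GD gains
        specs = []
        for _ in range(14):
            tK = float(np.round(0.5 + rng.uniform(-0.01, 0.01), 3))
            specs.append((2, 1, (1 - tK, tK), "gd_member"))
        for _ in range(5):
            tK = float(np.round(rng.uniform(0.05, 0.12), 3))
            specs.append((2, 1, (1 - tK, tK), "post_gd"))
        for _ in range(2):
            tK = float(np.round(rng.uniform(0.85, 0.92), 3))
            specs.append((2, 1, (1 - tK, tK), "pre_gd"))

    seg_rows, truth = _fixture_segment_rows(specs)
    seg_df = pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS)
    seg_df.to_csv(out / "segments.tsv", sep="\t", index=False)

    ssnv_rows = []
    for seg, info in zip(seg_rows, truth):
        cn = CNConfig(nt=info["nt"], nb=info["nb"])
        A = enumerate_histories(cn)[0]
        cfg = SimConfig(A=A, t=TimeFractions(np.array(info["t_true"])),
                        M=M, P=purity, mean_depth=depth)
        table = simulate_ssnvs(cfg, rng)
        positions = np.sort(rng.choice(
            np.arange(seg["start"], seg["end"]), size=len(table), replace=False))
        for p, m, d in zip(positions, table.m, table.d):
            ssnv_rows.append({"chrom": "1", "pos": int(p), "ref": "A", "alt": "T",
                              "t_alt_count": int(m), "t_depth": int(d)})
    pd.DataFrame(ssnv_rows, columns=SSNV_COLUMNS).to_csv(
        out / "ssnvs.tsv", sep="\t", index=False)
    (out / "purity.txt").write_text(f"{purity}\n")
    (out / "truth.json").write_text(json.dumps(
        {"scenario": scenario, "seed": seed, "purity": purity, "segments": truth},
        indent=2) + "\n")
    return out


def _make_cohort_fixture(out: Path, rng: np.random.Generator,
                         n_patients: int = 12, n_bins: int = 60) -> Path:
    """Cohort timing tables where bins 5-7 initiate recurrently early."""
    manifest = []
    for p in range(n_patients):
        t0 = rng.uniform(0.0, 1.0, size=n_bins)
        t0[5:8] = rng.uniform(0.0, 0.1, size=3)
        df = pd.DataFrame({
            "chrom": "1",
            "bin_start": np.arange(n_bins) * 1_000_000 + 1,
            "bin_end": (np.arange(n_bins) + 1) * 1_000_000,
            "t0": np.round(t0, 6),
        })
        fname = f"patient_{p:02d}_timing.tsv"
        df.to_csv(out / fname, sep="\t", index=False)
        manifest.append({"patient": f"P{p:02d}", "timing_file": fname})
    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(
        {"scenario": "cohort_recurrence", "early_bins": [5, 6, 7]}, indent=2) + "\n")
    return out
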