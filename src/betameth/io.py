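"""Readers and writers for the package's text formats.

Formats
-------
counts table
    Header line of whitespace-separated sample names; each body line is a
    site key ``chrom:pos:strand:context`` (1-based position) followed by
    2*s integers alternating (total, methylated) per sample.
design matrix
    Header line of factor names (first should be the intercept "base");
    each row is a sample name followed by 0/1 entries.
site results
    Tab-separated BED-like rows: chrom, start (0-based), end, name
    ``context:strand``, raw p, combined p, adjusted p, group-A level,
    group-B level. ``NA`` marks untestable / not-yet-computed values.
regions
    BED6+1: chrom, start, end, ``dmr:<n_cpgs>:<n_sig>``, log-odds score,
    strand ``.``, minimum methylation difference.

All BED output is 0-based half-open and sorted.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np

from .tables import CountTable, DesignMatrix, SiteKey, SiteResult

if TYPE_CHECKING:  # pragma: no cover
    from .regions import DMRegion


class ParseError(ValueError):
    """Raised on malformed input files; the message names the line."""


def _fmt(x: float, digits: int | None = None) -> str:
    """NA-aware float formatting; default is the shortest round-trippable
    representation so staged runs reproduce in-memory runs exactly."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return str(float(x)) if digits is None else f"{x:.{digits}g}"


def _parse_na(token: str) -> float:
    return float("nan") if token.upper() in ("NA", "NAN") else float(token)


def _parse_site_key(token: str, lineno: int) -> SiteKey:
    parts = token.split(":")
    if len(parts) != 4:
        raise ParseError(
            f"line {lineno}: malformed site key {token!r} "
            "(expected chrom:pos:strand:context)"
        )
    chrom, pos_s, strand, context = parts
    try:
        pos = int(pos_s)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer position in key {token!r}") from None
    try:
        return SiteKey(chrom=chrom, pos=pos, strand=strand, context=context)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def read_counts(path: str | Path) -> CountTable:
    """Parse a counts table; validation failures name the offending line."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError("line 1: empty header (expected sample names)")
        samples = header.split()
        s = len(samples)
        sites: list[SiteKey] = []
        totals: list[list[int]] = []
        meths: list[list[int]] = []
        seen: set[SiteKey] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 1 + 2 * s:
                raise ParseError(
                    f"line {lineno}: expected {1 + 2 * s} fields "
                    f"({s} samples), got {len(fields)}"
                )
            key = _parse_site_key(fields[0], lineno)
            if key in seen:
                raise ParseError(f"line {lineno}: duplicate site {key}")
            seen.add(key)
            try:
                nums = [int(x) for x in fields[1:]]
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer count") from None
            tot, met = nums[0::2], nums[1::2]
            for t_i, m_i in zip(tot, met):
                if t_i < 0 or m_i < 0:
                    raise ParseError(f"line {lineno}: negative count")
                if m_i > t_i:
                    raise ParseError(f"line {lineno}: meth exceeds total")
            sites.append(key)
            totals.append(tot)
            meths.append(met)
    keys = [(k.chrom, k.pos) for k in sites]
    if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
        raise ParseError("sites are not sorted by (chrom, pos)")
    shape = (len(sites), s)
    return CountTable(
        sites=sites,
        samples=samples,
        totals=np.array(totals, dtype=np.int64).reshape(shape),
        meths=np.array(meths, dtype=np.int64).reshape(shape),
    )


def write_counts(table: CountTable, path: str | Path) -> None:
    """Inverse of :func:`read_counts` (round-trips bit-exactly)."""
    with Path(path).open("w") as fh:
        fh.write(" ".join(table.samples) + "\n")
        for r, key in enumerate(table.sites):
            pairs = " ".join(
                f"{table.totals[r, c]} {table.meths[r, c]}"
                for c in range(table.n_samples)
            )
            fh.write(f"{key} {pairs}\n")


def read_design(path: str | Path, counts: CountTable | None = None) -> DesignMatrix:
    """Parse a design matrix, optionally checking samples against a table."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError("line 1: empty header (expected factor names)")
        factors = header.split()
        samples: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 1 + len(factors):
                raise ParseError(
                    f"line {lineno}: expected sample name plus "
                    f"{len(factors)} entries, got {len(fields) - 1}"
                )
            samples.append(fields[0])
            row = []
            for tok in fields[1:]:
                if tok not in ("0", "1"):
                    raise ParseError(f"line {lineno}: non-binary design entry {tok!r}")
                row.append(int(tok))
            rows.append(row)
    try:
        design = DesignMatrix(
            samples=samples, factors=factors,
            X=np.array(rows, dtype=np.int64).reshape(len(samples), len(factors)),
        )
    except ValueError as exc:
        raise ParseError(str(exc)) from None
    if counts is not None:
        design.check_samples(counts)
    return design


def write_design(design: DesignMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(" ".join(design.factors) + "\n")
        for i, name in enumerate(design.samples):
            fh.write(name + " " + " ".join(str(v) for v in design.X[i]) + "\n")


def write_site_results(results: Sequence[SiteResult], path: str | Path) -> None:
    """Write the per-site TSV, BED-sorted, with NA for untestable sites."""
    ordered = sorted(results, key=lambda r: (r.key.chrom, r.key.pos, r.key.strand))
    with Path(path).open("w") as fh:
        for res in ordered:
            k = res.key
            fh.write(
                "\t".join(
                    [
                        k.chrom,
                        str(k.pos - 1),
                        str(k.pos),
                        f"{k.context}:{k.strand}",
                        _fmt(res.p_raw),
                        _fmt(res.p_combined),
                        _fmt(res.p_adjusted),
                        _fmt(res.meth_a),
                        _fmt(res.meth_b),
                    ]
                )
                + "\n"
            )


def read_site_results(path: str | Path) -> list[SiteResult]:
    results: list[SiteResult] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, start_s, _end, name = fields[:4]
            context, _, strand = name.rpartition(":")
            key = SiteKey(chrom=chrom, pos=int(start_s) + 1, strand=strand,
                          context=context or "CpG")
            results.append(
                SiteResult(
                    key=key,
                    p_raw=_parse_na(fields[4]),
                    p_combined=_parse_na(fields[5]),
                    p_adjusted=_parse_na(fields[6]),
                    meth_a=_parse_na(fields[7]),
                    meth_b=_parse_na(fields[8]),
                )
            )
    return results


def write_regions(regions: Iterable["DMRegion"], path: str | Path) -> None:
    """Write DM regions as BED6+1 (score = region log-odds ratio)."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with Path(path).open("w") as fh:
        for reg in ordered:
            fh.write(
                "\t".join(
                    [
                        reg.chrom,
                        str(reg.start),
                        str(reg.end),
                        f"dmr:{reg.n_cpgs}:{reg.n_sig}",
                        _fmt(reg.log_odds, 4),
                        ".",
                        _fmt(reg.min_meth_diff, 4),
                    ]
                )
                + "\n"
            )


def write_truth_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write simulated true DM-region spans as a sorted 3-column BED."""
    with Path(path).open("w") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")
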