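"""Reading and writing genotype data sets and map tables.

Two input carriers are supported: VCF (the usual output of SNP-calling
pipelines; parents are named samples) and a plain-text "outcross raw" marker
table.  The raw grammar is::

    data type outcross
    <n_progeny> <n_markers>
    *<name> <cross_code> <call1>,<call2>,...,<callN>

with calls in ``{aa, ab, bb, -}`` and cross codes ``B3.7``, ``D1.10``,
``D2.15``.  Physical positions from VCF are not used by the mapping method
(linkage only), so they are not retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import (
    AA, AB, MISSING, GT_CODES, GT_NAMES,
    CrossType, MarkerData, NonInformativeError, classify_cross_type,
)

log = logging.getLogger(__name__)

__all__ = [
    "PopulationDataset", "RawFormatError",
    "read_raw_dataset", "write_raw_dataset",
    "vcf_to_dataset", "write_map_tables",
]

RAW_HEADER = "data type outcross"


class RawFormatError(ValueError):
    """Malformed outcross-raw input; message carries the line number."""


@dataclass
class PopulationDataset:
    """All markers and progeny of one F1 full-sib cross."""

    population_id: str
    female_id: str
    male_id: str
    progeny_ids: list[str]
    markers: list[MarkerData] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker names: {dup[:5]}")
        n = self.n_progeny
        for m in self.markers:
            if m.n_progeny != n:
                raise ValueError(
                    f"marker {m.name}: {m.n_progeny} calls for {n} progeny"
                )
        self._by_name = {m.name: m for m in self.markers}

    @property
    def n_progeny(self) -> int:
        return len(self.progeny_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker(self, name: str) -> MarkerData:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def subset(self, names: list[str]) -> "PopulationDataset":
        """New dataset restricted to ``names`` (kept in the given order)."""
        return PopulationDataset(
            population_id=self.population_id,
            female_id=self.female_id,
            male_id=self.male_id,
            progeny_ids=list(self.progeny_ids),
            markers=[self._by_name[n] for n in names],
        )

    def add_marker(self, marker: MarkerData) -> None:
        if marker.name in self._by_name:
            raise ValueError(f"duplicate marker name {marker.name}")
        if marker.n_progeny != self.n_progeny:
            raise ValueError(
                f"marker {marker.name}: {marker.n_progeny} calls for "
                f"{self.n_progeny} progeny"
            )
        self.markers.append(marker)
        self._by_name[marker.name] = marker


# Parent genotypes implied by a cross code (the raw format stores the code,
# not the parental calls; "a" = reference coding).
_CODE_PARENTS = {
    CrossType.B3_7: ("ab", "ab"),
    CrossType.D1_10: ("ab", "aa"),
    CrossType.D2_15: ("aa", "ab"),
}


def read_raw_dataset(
    path,
    population_id: str = "pop1",
    female_id: str = "P1",
    male_id: str = "P2",
) -> PopulationDataset:
    """Parse an outcross-raw file into a :class:`PopulationDataset`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != RAW_HEADER:
        raise RawFormatError(f"{path}:1: expected header {RAW_HEADER!r}")
    if len(lines) < 2:
        raise RawFormatError(f"{path}:2: missing dimensions line")
    try:
        n_progeny, n_markers = (int(x) for x in lines[1].split())
    except ValueError as exc:
        raise RawFormatError(
            f"{path}:2: dimensions line must be '<n_progeny> <n_markers>'"
        ) from exc

    markers: list[MarkerData] = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3 or not parts[0].startswith("*"):
            raise RawFormatError(
                f"{path}:{lineno}: expected '*<name> <code> <calls>'"
            )
        name = parts[0][1:]
        try:
            code = CrossType(parts[1])
        except ValueError as exc:
            raise RawFormatError(
                f"{path}:{lineno}: unknown cross code {parts[1]!r}"
            ) from exc
        tokens = parts[2].split(",")
        if len(tokens) != n_progeny:
            raise RawFormatError(
                f"{path}:{lineno}: marker {name} has {len(tokens)} calls, "
                f"header says {n_progeny}"
            )
        try:
            calls = np.array([GT_CODES[t] for t in tokens], dtype=np.int8)
        except KeyError as exc:
            raise RawFormatError(
                f"{path}:{lineno}: bad genotype token {exc.args[0]!r}"
            ) from exc
        female_gt, male_gt = _CODE_PARENTS[code]
        try:
            markers.append(
                MarkerData(name=name, female_gt=female_gt, male_gt=male_gt,
                           calls=calls, cross_type=code)
            )
        except ValueError as exc:
            raise RawFormatError(f"{path}:{lineno}: {exc}") from exc

    if len(markers) != n_markers:
        raise RawFormatError(
            f"{path}: header says {n_markers} markers, found {len(markers)}"
        )
    progeny_ids = [f"{population_id}_{i + 1:03d}" for i in range(n_progeny)]
    return PopulationDataset(population_id, female_id, male_id,
                             progeny_ids, markers)


def write_raw_dataset(dataset: PopulationDataset, path) -> None:
    """Write ``dataset`` in canonical outcross-raw text (round-trip stable)."""
    if dataset.n_progeny == 0:
        raise ValueError("dataset has no progeny; nothing to map")
    path = Path(path)
    out = [RAW_HEADER, f"{dataset.n_progeny} {dataset.n_markers}"]
    for m in dataset.markers:
        calls = ",".join(GT_NAMES[int(v)] for v in m.calls)
        out.append(f"*{m.name} {m.cross_type.value} {calls}")
    path.write_text("\n".join(out) + "\n")


def _gt_from_alleles(alleles: tuple) -> str | None:
    """Unphased genotype string from a cyvcf2 genotype tuple, or None."""
    a = [x for x in alleles[:2] if x is not None and x >= 0]
    if len(a) != 2:
        return None
    return GT_NAMES[int(a[0] > 0) + int(a[1] > 0)]


def vcf_to_dataset(
    vcf_path,
    female_id: str,
    male_id: str,
    population_id: str = "pop1",
) -> PopulationDataset:
    """Import biallelic SNPs from a VCF with named parent samples.

    REF is coded "a" and ALT "b".  Multiallelic records, non-SNPs, records
    where either parent call is missing and records where neither parent is
    heterozygous are dropped (counts logged).  Progeny are all samples except
    the parents.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for pid in (female_id, male_id):
        if pid not in samples:
            raise ValueError(f"parent sample {pid!r} not found in {vcf_path}")
    fi, mi = samples.index(female_id), samples.index(male_id)
    progeny_idx = [i for i, s in enumerate(samples)
                   if s not in (female_id, male_id)]
    progeny_ids = [samples[i] for i in progeny_idx]

    markers: list[MarkerData] = []
    dropped = {"multiallelic": 0, "parent_missing": 0,
               "non_informative": 0, "bad_progeny_call": 0}
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            dropped["multiallelic"] += 1
            continue
        gts = rec.genotypes
        female_gt = _gt_from_alleles(tuple(gts[fi]))
        male_gt = _gt_from_alleles(tuple(gts[mi]))
        if female_gt is None or male_gt is None:
            dropped["parent_missing"] += 1
            continue
        if female_gt == "bb" or male_gt == "bb":
            # recode so the shared reference is "a": swap alleles at this site
            swap = True
        else:
            swap = False

        def _recode(g: str | None) -> int:
            if g is None:
                return MISSING
            v = GT_CODES[g]
            return 2 - v if swap and v != MISSING else v

        f_v = _recode(female_gt)
        m_v = _recode(male_gt)
        f_gt, m_gt = GT_NAMES[f_v], GT_NAMES[m_v]
        if f_gt != "ab" and m_gt != "ab":
            dropped["non_informative"] += 1
            continue
        calls = np.array(
            [_recode(_gt_from_alleles(tuple(gts[i]))) for i in progeny_idx],
            dtype=np.int8,
        )
        name = rec.ID or f"{rec.CHROM}_{rec.POS}"
        try:
            markers.append(MarkerData(name=name, female_gt=f_gt,
                                      male_gt=m_gt, calls=calls))
        except ValueError:
            dropped["bad_progeny_call"] += 1
    total_dropped = sum(dropped.values())
    if total_dropped:
        log.info("vcf_to_dataset(%s): dropped %d records (%s)",
                 vcf_path, total_dropped, dropped)
    return PopulationDataset(population_id, female_id, male_id,
                             progeny_ids, markers)


def write_map_tables(map_table: pd.DataFrame, out_dir) -> list[Path]:
    """Write one TSV per linkage group plus a summary TSV.

    ``map_table`` must have columns ``linkage_group``, ``marker_name``,
    ``position_cM``, ``cross_type``, ``provenance``.  The summary mirrors a
    per-group description (group, marker count, length in cM, mean
    inter-marker distance; NA for single-marker groups).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    required = {"linkage_group", "marker_name", "position_cM",
                "cross_type", "provenance"}
    missing_cols = required - set(map_table.columns)
    if missing_cols:
        raise ValueError(f"map table missing columns {sorted(missing_cols)}")

    written: list[Path] = []
    summary_rows = []
    for gid, grp in map_table.groupby("linkage_group", sort=True):
        grp = grp.sort_values(["position_cM", "marker_name"],
                              kind="mergesort").copy()
        grp["position_cM"] = grp["position_cM"] - grp["position_cM"].iloc[0]
        p = out_dir / f"group_{gid}.tsv"
        grp.to_csv(p, sep="\t", index=False, float_format="%.4f")
        written.append(p)
        n = len(grp)
        length = float(grp["position_cM"].iloc[-1])
        density = length / (n - 1) if n > 1 else float("nan")
        summary_rows.append({
            "linkage_group": gid, "n_markers": n,
            "length_cM": round(length, 4),
            "mean_intermarker_cM": round(density, 4) if n > 1 else np.nan,
        })
    summary = pd.DataFrame(summary_rows)
    p = out_dir / "summary.tsv"
    summary.to_csv(p, sep="\t", index=False, na_rep="NA")
    written.append(p)
    return written
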