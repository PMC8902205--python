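"""Data model and file I/O for genotype, trait, and SNP-panel tables.

The pipeline's primary input is a table of unphased diploid calls
(individual x locus, cells like ``"CA"``), a trait table of body
measurements with age-class and sire identifiers, and a panel table
defining each SNP's two alleles.  Calls are unordered allele pairs and
are stored canonically with the reference allele first; missing
genotypes are encoded as an empty field or ``"NN"``, missing traits as
empty fields.

A minimal VCF v4.2 rendering (CHROM, POS, ID, REF, ALT, GT) is emitted
alongside the delimited tables so genotypes interoperate with standard
variant tooling; positions default to the 1-based coordinates embedded
in HGVS-style locus names on a placeholder contig, since the panel
carries no genome mapping.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .errors import ValidationError

TRAIT_NAMES = ("BL", "WH", "HH", "HG", "AGR", "HW", "PBW")
MISSING_CALLS = {"", "NN", "N", "..", "--", None}
VALID_BASES = frozenset("ACGT")
_LOCUS_NAME_RE = re.compile(r"g\.?\s*(\d+)\s*([ACGT])\s*>\s*([ACGT])")


@dataclass(frozen=True)
class SnpDef:
    """Definition of one biallelic SNP in the panel.

    ``locus_id`` is a short HGVS-style name such as ``"g.5070C>A"``; the
    embedded coordinate is a label only and is never used arithmetically.
    """

    locus_id: str
    allele_ref: str
    allele_alt: str
    region: str = "other"
    chrom: str = "candidate_gene"
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.allele_ref not in VALID_BASES or self.allele_alt not in VALID_BASES:
            raise ValidationError(
                f"locus {self.locus_id}: alleles must be one of A,C,G,T, "
                f"got {self.allele_ref!r}/{self.allele_alt!r}"
            )
        if self.allele_ref == self.allele_alt:
            raise ValidationError(f"locus {self.locus_id}: ref and alt allele are identical")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_ref, self.allele_alt)

    def canonical_call(self, call: str) -> str:
        """Return the unordered call with the reference allele first."""
        a, b = call[0], call[1]
        for x in (a, b):
            if x not in self.alleles:
                raise ValidationError(
                    f"allele {x!r} is not an allele of locus {self.locus_id} "
                    f"({self.allele_ref}/{self.allele_alt})"
                )
        if a == b:
            return a + b
        return self.allele_ref + self.allele_alt

    @classmethod
    def from_locus_name(cls, name: str, region: str = "other", pos: int | None = None) -> "SnpDef":
        """Parse ref/alt (and a default position) out of a ``g.244C>G``-style name."""
        m = _LOCUS_NAME_RE.search(name)
        if m is None:
            raise ValidationError(
                f"cannot parse alleles from locus name {name!r}; expected e.g. 'g.244C>G'"
            )
        coord, ref, alt = m.groups()
        return cls(
            locus_id=name.strip(),
            allele_ref=ref,
            allele_alt=alt,
            region=region,
            pos=pos if pos is not None else int(coord),
        )


@dataclass
class GenotypeMatrix:
    """Unphased diploid calls for ``n`` individuals at ``L`` biallelic loci.

    ``calls`` is a pandas DataFrame indexed by individual id with one
    column per panel locus; cells are canonical two-character strings or
    ``None`` for missing.
    """

    individual_ids: list[str]
    panel: list[SnpDef]
    calls: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    @property
    def locus_ids(self) -> list[str]:
        return [s.locus_id for s in self.panel]

    def snp(self, locus_id: str) -> SnpDef:
        for s in self.panel:
            if s.locus_id == locus_id:
                return s
        raise KeyError(locus_id)

    def validate(self) -> None:
        ids = self.individual_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate individual id(s): {dupes}")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("duplicate locus id in panel")
        if list(self.calls.index) != ids or list(self.calls.columns) != self.locus_ids:
            raise ValidationError("calls frame is not aligned with ids/panel")
        for snp in self.panel:
            col = self.calls[snp.locus_id]
            for ind, call in col.items():
                if call is None:
                    continue
                if len(call) != 2:
                    raise ValidationError(
                        f"individual {ind}, locus {snp.locus_id}: malformed call {call!r}"
                    )
                try:
                    snp.canonical_call(call)
                except ValidationError as exc:
                    raise ValidationError(f"individual {ind}: {exc}") from None

    @classmethod
    def from_calls(
        cls,
        individual_ids: Sequence[str],
        panel: Sequence[SnpDef],
        raw_calls: Mapping[str, Sequence[str | None]] | pd.DataFrame,
    ) -> "GenotypeMatrix":
        """Build a matrix from raw (possibly unordered) calls, canonicalizing each cell."""
        ids = [str(i) for i in individual_ids]
        frame = pd.DataFrame(raw_calls, index=ids) if not isinstance(raw_calls, pd.DataFrame) else raw_calls
        frame = frame.reindex(index=ids, columns=[s.locus_id for s in panel])
        out = {}
        for snp in panel:
            col = []
            for ind, raw in frame[snp.locus_id].items():
                if raw is None or (isinstance(raw, float) and pd.isna(raw)):
                    col.append(None)
                    continue
                raw = str(raw).strip().upper()
                if raw in MISSING_CALLS:
                    col.append(None)
                    continue
                if len(raw) != 2:
                    raise ValidationError(
                        f"individual {ind}, locus {snp.locus_id}: malformed call {raw!r}"
                    )
                try:
                    col.append(snp.canonical_call(raw))
                except ValidationError as exc:
                    raise ValidationError(f"individual {ind}: {exc}") from None
            out[snp.locus_id] = col
        gm = cls(ids, list(panel), pd.DataFrame(out, index=ids, columns=[s.locus_id for s in panel]))
        gm.validate()
        return gm

    def complete_cases(self, loci: Sequence[str] | None = None) -> "GenotypeMatrix":
        """Subset to individuals with no missing call at the chosen loci (listwise)."""
        loci = list(loci) if loci is not None else self.locus_ids
        sub = self.calls[loci]
        keep = sub.notna().all(axis=1)
        ids = [i for i, k in zip(self.individual_ids, keep) if k]
        panel = [self.snp(l) for l in loci]
        return GenotypeMatrix(ids, panel, self.calls.loc[ids, loci])

    def genotype_counts(self, locus_id: str) -> tuple[int, int, int]:
        """Complete-case (ref-hom, het, alt-hom) counts at one locus."""
        snp = self.snp(locus_id)
        col = self.calls[locus_id].dropna()
        rr = snp.allele_ref * 2
        aa = snp.allele_alt * 2
        het = snp.allele_ref + snp.allele_alt
        counts = col.value_counts()
        return (int(counts.get(rr, 0)), int(counts.get(het, 0)), int(counts.get(aa, 0)))


@dataclass
class TraitTable:
    """Body-conformation measurements (cm) with age class and sire id per individual."""

    frame: pd.DataFrame  # index individual_id; columns age, sire, then TRAIT_NAMES

    def validate(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate individual id in trait table")
        for t in TRAIT_NAMES:
            if t not in self.frame.columns:
                raise ValidationError(f"trait table missing column {t}")
            vals = pd.to_numeric(self.frame[t], errors="coerce")
            bad = vals.dropna() <= 0
            if bad.any():
                raise ValidationError(
                    f"non-positive {t} value for individual(s) {list(bad[bad].index)}"
                )

    @property
    def individual_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]


@dataclass
class Dataset:
    """A genotype matrix joined with its trait table.

    Individuals present in only one of the two inputs are recorded in
    ``unmatched_genotype_only`` / ``unmatched_trait_only``; they are kept
    for genotype-only statistics but excluded from ``joined()`` views.
    """

    genotypes: GenotypeMatrix
    traits: TraitTable | None = None
    unmatched_genotype_only: list[str] = field(default_factory=list)
    unmatched_trait_only: list[str] = field(default_factory=list)

    def joined(self) -> pd.DataFrame:
        """Genotype calls and traits side by side for the matched individuals."""
        if self.traits is None:
            raise ValidationError("dataset has no trait table")
        common = [i for i in self.genotypes.individual_ids if i in set(self.traits.individual_ids)]
        g = self.genotypes.calls.loc[common]
        t = self.traits.frame.loc[common]
        return pd.concat([g, t], axis=1)


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV with delimiter auto-detection; first column is the row id."""
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        dialect = csv.Sniffer().sniff(sample, delimiters=",\t")
        sep = dialect.delimiter
    except csv.Error:
        sep = "\t" if "\t" in sample.splitlines()[0] else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_panel(path: str | Path) -> list[SnpDef]:
    """Load a SNP definition table.

    Requires a ``locus_id`` column; ``ref``/``alt``/``region``/``chrom``/``pos``
    are optional — missing alleles are parsed from the locus name itself.
    """
    df = _read_table(path)
    if "locus_id" not in df.columns:
        raise ValidationError("panel file needs a 'locus_id' column")
    panel = []
    for _, row in df.iterrows():
        name = row["locus_id"].strip()
        region = row.get("region", "") or "other"
        pos = int(row["pos"]) if row.get("pos", "") else None
        if row.get("ref", "") and row.get("alt", ""):
            panel.append(
                SnpDef(name, row["ref"].strip(), row["alt"].strip(), region,
                       row.get("chrom", "") or "candidate_gene", pos)
            )
        else:
            panel.append(SnpDef.from_locus_name(name, region=region, pos=pos))
    if len({s.locus_id for s in panel}) != len(panel):
        raise ValidationError("duplicate locus_id in panel file")
    return panel


def panel_from_header(locus_names: Sequence[str]) -> list[SnpDef]:
    """Build a panel directly from HGVS-style column names of a genotype table."""
    return [SnpDef.from_locus_name(n) for n in locus_names]


def load_genotypes(path: str | Path, panel: Sequence[SnpDef] | None = None) -> GenotypeMatrix:
    df = _read_table(path)
    id_col = df.columns[0]
    ids = [s.strip() for s in df[id_col]]
    locus_cols = [c for c in df.columns[1:]]
    if panel is None:
        panel = panel_from_header(locus_cols)
    else:
        missing = [s.locus_id for s in panel if s.locus_id not in locus_cols]
        if missing:
            raise ValidationError(f"genotype table lacks panel loci: {missing}")
        locus_cols = [s.locus_id for s in panel]
    raw = pd.DataFrame({c: list(df[c]) for c in locus_cols}, index=ids)
    return GenotypeMatrix.from_calls(ids, panel, raw)


def load_traits(path: str | Path) -> TraitTable:
    df = _read_table(path)
    id_col = df.columns[0]
    df = df.set_index(id_col)
    df.index = [str(i).strip() for i in df.index]
    for c in ("age", "sire"):
        if c not in df.columns:
            raise ValidationError(f"trait table needs an '{c}' column")
    for t in TRAIT_NAMES:
        if t in df.columns:
            df[t] = pd.to_numeric(df[t].replace("", None), errors="raise")
    tt = TraitTable(df)
    tt.validate()
    return tt


def load_dataset(
    genotype_path: str | Path,
    trait_path: str | Path | None = None,
    panel_path: str | Path | None = None,
) -> Dataset:
    """Load and join the three input tables into a validated :class:`Dataset`."""
    panel = load_panel(panel_path) if panel_path is not None else None
    gm = load_genotypes(genotype_path, panel)
    if trait_path is None:
        return Dataset(gm)
    tt = load_traits(trait_path)
    gset = set(gm.individual_ids)
    tset = set(tt.individual_ids)
    return Dataset(
        gm,
        tt,
        unmatched_genotype_only=sorted(gset - tset),
        unmatched_trait_only=sorted(tset - gset),
    )


def write_dataset(dataset: Dataset, out_dir: str | Path, sep: str = "\t") -> dict[str, Path]:
    """Write genotype/trait/panel tables plus a minimal VCF; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if sep == "\t" else "csv"
    paths: dict[str, Path] = {}

    gm = dataset.genotypes
    gpath = out / f"genotypes.{ext}"
    gframe = gm.calls.fillna("NN")
    gframe.insert(0, "individual_id", gm.individual_ids)
    gframe.to_csv(gpath, sep=sep, index=False)
    paths["genotypes"] = gpath

    ppath = out / f"panel.{ext}"
    pd.DataFrame(
        {
            "locus_id": [s.locus_id for s in gm.panel],
            "ref": [s.allele_ref for s in gm.panel],
            "alt": [s.allele_alt for s in gm.panel],
            "region": [s.region for s in gm.panel],
            "chrom": [s.chrom for s in gm.panel],
            "pos": [s.pos if s.pos is not None else "" for s in gm.panel],
        }
    ).to_csv(ppath, sep=sep, index=False)
    paths["panel"] = ppath

    if dataset.traits is not None:
        tpath = out / f"traits.{ext}"
        tframe = dataset.traits.frame.copy()
        tframe.insert(0, "individual_id", tframe.index)
        tframe.to_csv(tpath, sep=sep, index=False)
        paths["traits"] = tpath

    vpath = out / "genotypes.vcf"
    write_vcf(gm, vpath)
    paths["vcf"] = vpath
    return paths


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Render genotypes as VCF v4.2 (GT only, unphased, one sample per individual)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    contigs = []
    for s in gm.panel:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individual_ids))
    for idx, snp in enumerate(gm.panel):
        pos = snp.pos if snp.pos is not None else idx + 1
        gts = []
        for call in gm.calls[snp.locus_id]:
            if call is None:
                gts.append("./.")
            else:
                code = {snp.allele_ref: "0", snp.allele_alt: "1"}
                a, b = sorted(code[c] for c in call)
                gts.append(f"{a}/{b}")
        lines.append(
            f"{snp.chrom}\t{pos}\t{snp.locus_id}\t{snp.allele_ref}\t{snp.allele_alt}"
            f"\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path, panel: Sequence[SnpDef] | None = None) -> GenotypeMatrix:
    """Read genotypes back from a VCF produced by :func:`write_vcf` (GT subset only)."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    records = list(vf)
    if panel is None:
        panel = [
            SnpDef(
                rec.id or f"{rec.chrom}:{rec.pos}",
                rec.ref,
                rec.alts[0],
                chrom=rec.chrom,
                pos=rec.pos,
            )
            for rec in records
        ]
    raw: dict[str, list[str | None]] = {}
    for snp, rec in zip(panel, records):
        alleles = (snp.allele_ref, snp.allele_alt)
        col: list[str | None] = []
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                col.append(None)
            else:
                col.append("".join(alleles[a] for a in gt))
        raw[snp.locus_id] = col
    return GenotypeMatrix.from_calls(samples, panel, pd.DataFrame(raw, index=samples))
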