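"""Genotype readers and marker/sample quality control.

Implements the four QC filters applied before association testing: sample
call rate (>= 95% non-missing markers per individual), marker call rate
(>= 95% non-missing individuals per marker), an exact Hardy-Weinberg
equilibrium test (markers with p < 1e-6 removed; hard calls only), and a
minor-allele-frequency floor (MAF >= 5%).  Filters run in that order and a
:class:`QCReport` records the tally at each stage.

Genotypes are held as an n x p dosage matrix (minor-allele copies, 0-2;
NaN = missing).  Readers cover VCF (GT hard calls or DS dosages),
PLINK-style .ped/.map text, and a plain dosage CSV.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Subject-by-marker dosage matrix with marker metadata.

    ``dosage[i, k]`` is the allele-count (or imputed expected count) of the
    counted allele of marker k for subject i, NaN if missing.  ``hard_calls``
    is True when every non-missing entry is an integer genotype call.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray
    hard_calls: bool = True

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=[s for s, k in zip(self.samples, keep) if k],
            markers=self.markers,
            dosage=self.dosage[np.asarray(keep, bool)],
            hard_calls=self.hard_calls,
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep, bool)
        return GenotypeMatrix(
            samples=self.samples,
            markers=self.markers.loc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep],
            hard_calls=self.hard_calls,
        )

    def oriented_to_minor(self) -> "GenotypeMatrix":
        """Flip dosages so every marker counts its minor allele.

        Adds a ``minor_allele`` column to the marker table; markers already
        counting the minor allele are untouched.
        """
        d = self.dosage.copy()
        markers = self.markers.copy()
        freq = np.nanmean(d, axis=0) / 2.0
        flip = freq > 0.5
        d[:, flip] = 2.0 - d[:, flip]
        minor = []
        for k in range(self.n_markers):
            ref = markers["ref"].iloc[k] if "ref" in markers.columns else "A"
            alt = markers["alt"].iloc[k] if "alt" in markers.columns else "B"
            minor.append(ref if flip[k] else alt)
        markers["minor_allele"] = minor
        return GenotypeMatrix(samples=self.samples, markers=markers, dosage=d,
                              hard_calls=self.hard_calls)


@dataclass
class QCReport:
    """Stage-by-stage QC tally; marker counts partition the input."""

    n_samples_in: int = 0
    n_samples_removed_call_rate: int = 0
    n_samples_retained: int = 0
    n_markers_in: int = 0
    n_markers_removed_call_rate: int = 0
    n_markers_removed_hwe: int = 0
    n_markers_removed_maf: int = 0
    n_markers_retained: int = 0
    thresholds: dict = field(default_factory=dict)

    def validate(self) -> None:
        removed = (self.n_markers_removed_call_rate + self.n_markers_removed_hwe
                   + self.n_markers_removed_maf)
        if removed + self.n_markers_retained != self.n_markers_in:
            raise AssertionError("QC marker counts do not partition the input")
        if (self.n_samples_removed_call_rate + self.n_samples_retained
                != self.n_samples_in):
            raise AssertionError("QC sample counts do not partition the input")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# readers

def read_genotypes(path: str, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF, PLINK-style .ped/.map text, or dosage CSV.

    ``fmt`` is one of "vcf", "plink_text", "dosage_csv"; inferred from the
    file suffix when omitted.
    """
    p = Path(path)
    if fmt is None:
        if p.suffix in (".vcf",) or path.endswith(".vcf.gz"):
            fmt = "vcf"
        elif p.suffix == ".ped":
            fmt = "plink_text"
        else:
            fmt = "dosage_csv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "plink_text":
        return read_plink_text(path, str(p.with_suffix(".map")))
    if fmt == "dosage_csv":
        return read_dosage_csv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF; GT hard calls become alt-allele counts, DS dosages are
    preserved as reals.  Multi-allelic sites are skipped with a warning."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    rows = []
    any_dosage = False
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%s", var.CHROM, var.POS)
            continue
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, float).reshape(-1)
            d = np.where((d < 0) | (d > 2), np.nan, d)
            any_dosage = True
        else:
            gt = np.asarray(var.gt_types, int)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            d = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(int(var.POS))
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(d)
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                            "ref": refs, "alt": alts})
    dosage = (np.stack(rows, axis=1) if rows
              else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage,
                          hard_calls=not any_dosage)


def read_plink_text(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read PLINK-style .ped/.map text files (white-space separated).

    Alleles are counted against the first allele observed at each marker
    (orientation is resolved later by :meth:`GenotypeMatrix.oriented_to_minor`).
    '0' denotes a missing allele.
    """
    markers = pd.read_csv(map_path, sep=r"\s+", header=None,
                          names=["chrom", "id", "cm", "pos"])
    p = len(markers)
    samples, geno_rows = [], []
    counted: list[str | None] = [None] * p
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * p:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * p} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            row = np.full(p, np.nan)
            for k in range(p):
                a1, a2 = parts[6 + 2 * k], parts[7 + 2 * k]
                if a1 == "0" or a2 == "0":
                    continue
                if counted[k] is None:
                    counted[k] = a1
                row[k] = (a1 == counted[k]) + (a2 == counted[k])
            geno_rows.append(row)
    alleles = pd.DataFrame({"ref": ["0" if c is None else c for c in counted],
                            "alt": ["0"] * p})
    markers = pd.concat([markers[["id", "chrom", "pos"]], alleles], axis=1)
    # counted allele is stored as "ref"; dosage counts it, flip counts to the
    # conventional alt orientation so downstream minor-allele logic is uniform
    dosage = 2.0 - np.stack(geno_rows) if geno_rows else np.empty((0, p))
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage,
                          hard_calls=True)


def read_dosage_csv(path: str) -> GenotypeMatrix:
    """Plain dosage CSV: first column subject id, one column per marker id.

    An optional sidecar ``<path>.markers.csv`` with columns id, chrom, pos
    (and optionally ref/alt) supplies marker metadata.
    """
    df = pd.read_csv(path)
    samples = df.iloc[:, 0].astype(str).tolist()
    dosage = df.iloc[:, 1:].to_numpy(float)
    if np.any((dosage < 0) | (dosage > 2)):
        bad = np.argwhere((dosage < 0) | (dosage > 2))[0]
        raise ValueError(f"{path}: dosage outside [0,2] at row {bad[0] + 2}")
    ids = list(df.columns[1:])
    sidecar = Path(str(path) + ".markers.csv")
    if sidecar.exists():
        markers = pd.read_csv(sidecar)
    else:
        markers = pd.DataFrame({"id": ids, "chrom": "0",
                                "pos": np.arange(1, len(ids) + 1),
                                "ref": "A", "alt": "B"})
    hard = bool(np.all(np.isnan(dosage) | (dosage == np.round(dosage))))
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage,
                          hard_calls=hard)


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write hard calls as a minimal VCF 4.2 text file (GT field)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for k in range(G.n_markers):
            m = G.markers.iloc[k]
            gts = []
            for i in range(G.n_samples):
                d = G.dosage[i, k]
                gts.append("./." if (isinstance(d, float) and math.isnan(d))
                           else code[int(round(d))])
            fh.write(f"{m['chrom']}\t{m['pos']}\t{m['id']}\t{m.get('ref', 'A')}\t"
                     f"{m.get('alt', 'B')}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# filters

def sample_call_rate_filter(G: GenotypeMatrix, threshold: float = 0.95
                            ) -> tuple[GenotypeMatrix, list[str]]:
    """Remove samples whose fraction of non-missing markers is below threshold."""
    if G.n_markers == 0:
        return G, []
    call = 1.0 - np.mean(np.isnan(G.dosage), axis=1)
    keep = call >= threshold
    removed = [s for s, k in zip(G.samples, keep) if not k]
    return G.subset_samples(keep), removed


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value (conditional on allele counts).

    Sums the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count.  Monomorphic
    markers return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype observation required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    # unnormalized log-probabilities over feasible het counts (parity of rare)
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    lp = (hets * math.log(2.0) - gammaln(hom_r + 1.0) - gammaln(hets + 1.0)
          - gammaln(hom_c + 1.0))
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def marker_maf(dosage_col: np.ndarray) -> float:
    """Minor-allele frequency from non-missing dosages: min(m, 1-m), m = mean/2."""
    d = dosage_col[~np.isnan(dosage_col)]
    if d.size == 0:
        return float("nan")
    m = float(np.mean(d) / 2.0)
    return min(m, 1.0 - m)


def marker_filters(G: GenotypeMatrix, call_rate: float = 0.95,
                   hwe_alpha: float = 1e-6, maf_min: float = 0.05
                   ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker QC in order: call rate, HWE, MAF.

    HWE is tested on hard calls only; dosage data skip the HWE stage with a
    logged notice.  The report partitions markers over the three stages.
    """
    report = QCReport(
        n_samples_in=G.n_samples, n_samples_retained=G.n_samples,
        n_markers_in=G.n_markers,
        thresholds={"marker_call_rate": call_rate, "hwe_alpha": hwe_alpha,
                    "maf_min": maf_min},
    )
    d = G.dosage
    call = 1.0 - np.mean(np.isnan(d), axis=0) if G.n_samples else np.ones(G.n_markers)
    pass_call = call >= call_rate
    report.n_markers_removed_call_rate = int(np.sum(~pass_call))

    pass_hwe = pass_call.copy()
    if G.hard_calls:
        for k in np.flatnonzero(pass_call):
            col = d[:, k]
            col = col[~np.isnan(col)]
            counts = [int(np.sum(col == g)) for g in (0, 1, 2)]
            if hwe_exact_test(counts[2], counts[1], counts[0]) < hwe_alpha:
                pass_hwe[k] = False
    else:
        logger.info("dosage genotypes: HWE stage skipped")
    report.n_markers_removed_hwe = int(np.sum(pass_call & ~pass_hwe))

    pass_maf = pass_hwe.copy()
    for k in np.flatnonzero(pass_hwe):
        if marker_maf(d[:, k]) < maf_min:
            pass_maf[k] = False
    report.n_markers_removed_maf = int(np.sum(pass_hwe & ~pass_maf))
    report.n_markers_retained = int(np.sum(pass_maf))
    report.validate()
    return G.subset_markers(pass_maf), report


def run_qc(G: GenotypeMatrix, sample_call_rate: float = 0.95,
           marker_call_rate: float = 0.95, hwe_alpha: float = 1e-6,
           maf_min: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC cascade: sample call rate first, then the marker filters."""
    G1, removed = sample_call_rate_filter(G, sample_call_rate)
    G2, report = marker_filters(G1, marker_call_rate, hwe_alpha, maf_min)
    report.n_samples_in = G.n_samples
    report.n_samples_removed_call_rate = len(removed)
    report.n_samples_retained = G1.n_samples
    report.thresholds["sample_call_rate"] = sample_call_rate
    report.validate()
    return G2, report
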