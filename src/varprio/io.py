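"""Readers and writers: annotated multi-sample VCF, PED + status sidecar,
annotation TSV sidecar, candidate table and funnel report.

Annotation transport is configurable through a key map: site-level scores
come from INFO keys, per-sample read evidence from FORMAT keys.  A TSV
sidecar keyed by ``chrom:pos:ref:alt`` may be merged on top of (or instead
of) VCF-borne annotations.  Multi-allelic sites are decomposed into one
record per alt allele; per-sample genotypes are recomputed against that
alt allele only.  Missing annotation keys yield missing fields, never
defaults.
"""
from __future__ import annotations

import json
import math
import os
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .model import (
    AnnotationBundle,
    FilterFunnel,
    Genotype,
    Pedigree,
    PedigreeMember,
    PREDICTOR_DELETERIOUS,
    PREDICTOR_TOLERATED,
    PREDICTORS,
    RegionClass,
    SampleCall,
    Sex,
    Status,
    ValidationError,
    VariantRecord,
)


class VcfParseError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


#: canonical annotation-field name -> VCF INFO/FORMAT key used by the
#: bundled simulator; any mapping with the same canonical names works.
DEFAULT_KEY_MAP: dict[str, str] = {
    # site-level INFO keys
    "maf_1kg": "MAF1KG",
    "maf_exac_nontcga": "MAFEXAC",
    "maf_inhouse": "MAFIH",
    "cadd_phred": "CADD",
    "gerp": "GERP",
    "phastcons": "PHASTCONS",
    "mutation_taster": "MT",
    "polyphen2": "PPH2",
    "provean": "PROVEAN",
    "sift": "SIFT",
    "intolerance_inhouse": "ITOL_IH",
    "intolerance_esp": "ITOL_ESP",
    "intolerance_exac": "ITOL_EXAC",
    "regulome_rank": "REGDB",
    "haploreg_flags": "HAPLOREG",
    "mirsvr": "MIRSVR",
    "mirna_secondary": "MIRNA2",
    "region": "REGION",
    # per-sample FORMAT keys
    "depth": "DP",
    "alt_fwd": "ALTF",
    "alt_rev": "ALTR",
}

_INTOL_KEYS = {
    "intolerance_inhouse": "inhouse",
    "intolerance_esp": "esp",
    "intolerance_exac": "exac",
}

_DELETERIOUS_TOKENS = {"D", "deleterious", "damaging"}
_TOLERATED_TOKENS = {"T", "N", "B", "tolerated", "benign", "neutral"}


def _per_alt(value, alt_index: int, n_alts: int):
    """Pick the value for one alt allele from a possibly per-alt INFO value."""
    if isinstance(value, tuple):
        if len(value) == n_alts:
            return value[alt_index]
        if len(value) == 1:
            return value[0]
        if len(value) > alt_index:
            return value[alt_index]
        return None
    return value


def _as_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(v):
        return None
    # normalize to 6 significant digits: htslib stores INFO floats in 32
    # bits, so this makes text, binary and in-memory values agree exactly
    return float(format(v, ".6g"))


def _predictor_call(value) -> Optional[str]:
    if value is None:
        return None
    token = str(value).strip()
    if not token or token == ".":
        return None
    if token in _DELETERIOUS_TOKENS:
        return PREDICTOR_DELETERIOUS
    if token in _TOLERATED_TOKENS:
        return PREDICTOR_TOLERATED
    raise ValidationError(f"unrecognized predictor call token: {token!r}")


def _region_from(value) -> RegionClass:
    if value is None:
        return RegionClass.OTHER
    token = str(value).strip().lower()
    try:
        return RegionClass(token)
    except ValueError:
        return RegionClass.OTHER


def _genotype_against_alt(gt: Sequence[Optional[int]], alt_allele_index: int) -> Genotype:
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return Genotype.MISSING
    n_alt = sum(1 for a in gt if a == alt_allele_index)
    if n_alt >= 2:
        return Genotype.HOM_ALT
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_REF


def _format_int(sample, key: str, alt_index: int, n_alts: int) -> Optional[int]:
    if key not in sample:
        return None
    value = sample[key]
    if isinstance(value, tuple):
        if len(value) == n_alts + 1:  # Number=R -> ref + alts
            value = value[alt_index + 1]
        elif len(value) == n_alts:  # Number=A
            value = value[alt_index]
        elif value:
            value = value[0]
        else:
            return None
    if value is None:
        return None
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def _bundle_from_info(info_get, alt_index: int, n_alts: int, key_map: Mapping[str, str]) -> AnnotationBundle:
    def raw(name):
        key = key_map.get(name)
        if key is None:
            return None
        return _per_alt(info_get(key), alt_index, n_alts)

    predictor_calls = {}
    for pred, canonical in zip(("mutation_taster", "polyphen2", "provean", "sift"), PREDICTORS):
        call = _predictor_call(raw(pred))
        if call is not None:
            predictor_calls[canonical] = call

    intolerance = {}
    for name, source in _INTOL_KEYS.items():
        v = _as_float(raw(name))
        if v is not None:
            intolerance[source] = v

    flags_raw = raw("haploreg_flags")
    flags: frozenset[str] = frozenset()
    if flags_raw is not None:
        token = str(flags_raw).strip()
        if token and token != ".":
            flags = frozenset(t for t in token.split("|") if t)

    regulome = raw("regulome_rank")
    regulome = None if regulome in (None, ".", "") else str(regulome)

    mirna2_raw = raw("mirna_secondary")
    mirna2 = None
    if mirna2_raw is not None:
        mirna2 = str(mirna2_raw).strip() in ("1", "true", "True", "yes")

    return AnnotationBundle(
        maf_1kg=_as_float(raw("maf_1kg")),
        maf_exac_nontcga=_as_float(raw("maf_exac_nontcga")),
        maf_inhouse=_as_float(raw("maf_inhouse")),
        cadd_phred=_as_float(raw("cadd_phred")),
        gerp=_as_float(raw("gerp")),
        phastcons=_as_float(raw("phastcons")),
        predictor_calls=predictor_calls,
        intolerance_pct=intolerance,
        regulome_rank=regulome,
        haploreg_flags=flags,
        mirsvr=_as_float(raw("mirsvr")),
        mirna_secondary=mirna2,
    )


def read_annotated_vcf(
    path: str | os.PathLike,
    key_map: Optional[Mapping[str, str]] = None,
    samples: Optional[Sequence[str]] = None,
) -> list[tuple[VariantRecord, AnnotationBundle]]:
    """Read a multi-sample VCF into decomposed (record, annotations) pairs.

    Parameters
    ----------
    path:
        VCF v4.x file (plain text or bgzipped).
    key_map:
        Canonical annotation-field name -> INFO/FORMAT key.  Unmapped or
        absent keys yield missing annotation fields.
    samples:
        Expected cohort sample ids; a configuration error is raised if any
        is absent from the VCF header.
    """
    key_map = dict(DEFAULT_KEY_MAP if key_map is None else key_map)
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    vcf_samples = list(vf.header.samples)
    if not vcf_samples:
        raise ConfigurationError(f"VCF {path} has no sample columns")
    if samples is not None:
        missing = [s for s in samples if s not in vcf_samples]
        if missing:
            raise ConfigurationError(f"sample columns absent from VCF: {missing}")

    out: list[tuple[VariantRecord, AnnotationBundle]] = []
    line_no = 0
    try:
        for rec in vf:
            line_no += 1
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts):
                if alt is None or alt in ("*", "<*>"):
                    continue
                per_sample: dict[str, SampleCall] = {}
                for sid in vcf_samples:
                    sample = rec.samples[sid]
                    gt = sample.get("GT")
                    geno = _genotype_against_alt(gt, alt_index + 1)
                    per_sample[sid] = SampleCall(
                        genotype=geno,
                        depth=_format_int(sample, key_map.get("depth", "DP"), alt_index, len(alts)),
                        alt_fwd=_format_int(sample, key_map.get("alt_fwd", "ALTF"), alt_index, len(alts)),
                        alt_rev=_format_int(sample, key_map.get("alt_rev", "ALTR"), alt_index, len(alts)),
                    )
                bundle = _bundle_from_info(rec.info.get, alt_index, len(alts), key_map)
                region_key = key_map.get("region")
                region = _region_from(
                    _per_alt(rec.info.get(region_key), alt_index, len(alts))
                    if region_key
                    else None
                )
                filt = list(rec.filter.keys())
                upstream = ";".join(filt) if filt else None
                record = VariantRecord(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(alt),
                    region=region,
                    qual=None if rec.qual is None else float(rec.qual),
                    upstream_filter=upstream,
                    per_sample=per_sample,
                )
                out.append((record, bundle))
    except (ValueError, OSError) as exc:
        raise VcfParseError(
            f"malformed VCF {path} near data line {line_no + 1}: {exc}"
        ) from exc
    return out


# ---------------------------------------------------------------------------
# annotation TSV sidecar

_TSV_FLOAT_FIELDS = (
    "maf_1kg", "maf_exac_nontcga", "maf_inhouse",
    "cadd_phred", "gerp", "phastcons", "mirsvr",
)


def read_annotation_table(path: str | os.PathLike) -> dict[str, AnnotationBundle]:
    """Read a TSV annotation sidecar keyed by ``chrom:pos:ref:alt``.

    Columns use canonical field names; predictor columns hold categorical
    calls (D/T), ``haploreg_flags`` is pipe-joined, '.' or empty = missing.
    """
    bundles: dict[str, AnnotationBundle] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "variant_key" not in header:
            raise ValidationError(f"annotation table {path} lacks a variant_key column")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = dict(zip(header, line.rstrip("\n").split("\t")))

            def get(name):
                v = fields.get(name, "")
                return None if v in ("", ".") else v

            kwargs = {f: _as_float(get(f)) for f in _TSV_FLOAT_FIELDS}
            preds = {}
            for p in PREDICTORS:
                call = _predictor_call(get(p))
                if call is not None:
                    preds[p] = call
            intol = {}
            for col, source in (("intolerance_inhouse", "inhouse"),
                                ("intolerance_esp", "esp"),
                                ("intolerance_exac", "exac")):
                v = _as_float(get(col))
                if v is not None:
                    intol[source] = v
            flags_raw = get("haploreg_flags")
            flags = frozenset(t for t in flags_raw.split("|") if t) if flags_raw else frozenset()
            mirna2_raw = get("mirna_secondary")
            mirna2 = None if mirna2_raw is None else mirna2_raw in ("1", "true", "True")
            try:
                bundles[fields["variant_key"]] = AnnotationBundle(
                    predictor_calls=preds,
                    intolerance_pct=intol,
                    regulome_rank=get("regulome_rank"),
                    haploreg_flags=flags,
                    mirna_secondary=mirna2,
                    **kwargs,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{ln}: {exc}") from exc
    return bundles


def _merge_bundle(base: AnnotationBundle, extra: AnnotationBundle) -> AnnotationBundle:
    """Overlay non-missing fields of ``extra`` on ``base``."""
    return AnnotationBundle(
        maf_1kg=extra.maf_1kg if extra.maf_1kg is not None else base.maf_1kg,
        maf_exac_nontcga=(
            extra.maf_exac_nontcga if extra.maf_exac_nontcga is not None else base.maf_exac_nontcga
        ),
        maf_inhouse=extra.maf_inhouse if extra.maf_inhouse is not None else base.maf_inhouse,
        cadd_phred=extra.cadd_phred if extra.cadd_phred is not None else base.cadd_phred,
        gerp=extra.gerp if extra.gerp is not None else base.gerp,
        phastcons=extra.phastcons if extra.phastcons is not None else base.phastcons,
        predictor_calls={**base.predictor_calls, **extra.predictor_calls},
        intolerance_pct={**base.intolerance_pct, **extra.intolerance_pct},
        regulome_rank=extra.regulome_rank if extra.regulome_rank is not None else base.regulome_rank,
        haploreg_flags=base.haploreg_flags | extra.haploreg_flags,
        mirsvr=extra.mirsvr if extra.mirsvr is not None else base.mirsvr,
        mirna_secondary=(
            extra.mirna_secondary if extra.mirna_secondary is not None else base.mirna_secondary
        ),
    )


def merge_annotation_sidecar(
    pairs: Iterable[tuple[VariantRecord, AnnotationBundle]],
    sidecar: Mapping[str, AnnotationBundle],
) -> list[tuple[VariantRecord, AnnotationBundle]]:
    out = []
    for rec, bundle in pairs:
        extra = sidecar.get(rec.key)
        out.append((rec, _merge_bundle(bundle, extra) if extra is not None else bundle))
    return out


# ---------------------------------------------------------------------------
# pedigree + status sidecar

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODES = {"2": True, "1": False}


def read_pedigree(
    ped_path: str | os.PathLike,
    status_path: Optional[str | os.PathLike] = None,
) -> Pedigree:
    """Read a 6-column PED file plus an optional status sidecar TSV.

    Members absent from the sidecar get status UNINFORMATIVE and
    ``sequenced=False``; sidecar rows naming unknown individuals are a
    validation error.
    """
    members: dict[str, PedigreeMember] = {}
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ValidationError(f"{ped_path}:{ln}: expected 6 PED columns, got {len(cols)}")
            fam, iid, fid, mid, sex, pheno = cols[:6]
            members[iid] = PedigreeMember(
                member_id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                affected=_PHENO_CODES.get(pheno),
                family_id=fam,
            )
    if status_path is not None:
        with open(status_path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("individual_id"):
                    continue
                cols = line.split("\t") if "\t" in line else line.split()
                if len(cols) < 2:
                    raise ValidationError(f"{status_path}:{ln}: expected (individual_id, status)")
                iid, status_token = cols[0], cols[1]
                if iid not in members:
                    raise ValidationError(
                        f"{status_path}:{ln}: status for unknown individual {iid!r}"
                    )
                try:
                    status = Status(status_token)
                except ValueError:
                    raise ValidationError(
                        f"{status_path}:{ln}: unknown status {status_token!r}"
                    ) from None
                members[iid].status = status
                members[iid].sequenced = True
    return Pedigree(members.values())


def write_pedigree(ped: Pedigree, ped_path: str | os.PathLike, status_path: str | os.PathLike) -> None:
    with open(ped_path, "w") as fh:
        for mid in sorted(ped.members):
            m = ped.members[mid]
            sex = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}[m.sex]
            pheno = {True: "2", False: "1", None: "0"}[m.affected]
            fh.write(
                f"{m.family_id}\t{m.member_id}\t{m.father_id or 0}\t{m.mother_id or 0}\t{sex}\t{pheno}\n"
            )
    with open(status_path, "w") as fh:
        fh.write("individual_id\tstatus\n")
        for mid in sorted(ped.members):
            m = ped.members[mid]
            if m.sequenced:
                fh.write(f"{m.member_id}\t{m.status.value}\n")


# ---------------------------------------------------------------------------
# outputs

CANDIDATE_COLUMNS = [
    "rank", "chrom", "pos", "ref", "alt", "vclass", "region", "branch",
    "qual", "filter",
    "maf_1kg", "maf_exac_nontcga", "maf_inhouse",
    "cadd_phred", "cadd_tier", "gerp", "phastcons", "conservation_pass",
    "mutation_taster", "polyphen2", "provean", "sift",
    "intolerance_inhouse", "intolerance_esp", "intolerance_exac",
    "regulome_rank", "haploreg_flags", "mirsvr", "mirna_target",
    "flags", "stage_verdicts",
]


def _fmt(v) -> str:
    if v is None:
        return "."
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return format(v, "g")
    if isinstance(v, frozenset) or isinstance(v, (set, list, tuple)):
        return "|".join(sorted(map(str, v))) if v else "."
    return str(v)


def write_outputs(candidates: Sequence, funnel: FilterFunnel, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the candidate TSV and machine-readable funnel JSON.

    ``candidates`` are pipeline traces (see :mod:`varprio.pipeline`) carrying
    per-stage verdicts.  Returns the paths written.  Deterministic: identical
    inputs produce byte-identical files.
    """
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
        cand_path = os.path.join(out_dir, "candidates.tsv")
        with open(cand_path, "w") as fh:
            fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
            for trace in candidates:
                fh.write("\t".join(_fmt(v) for v in trace.as_row()) + "\n")
        funnel_path = os.path.join(out_dir, "funnel.json")
        with open(funnel_path, "w") as fh:
            json.dump(funnel.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write outputs to {out_dir}: {exc}") from exc
    return {"candidates": cand_path, "funnel": funnel_path}
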