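"""Synthetic labeled radiology-report corpora.

The study's clinical reports are PHI-protected and cannot be shipped, so
this module generates corpora with the same statistical structure: ~26%
high-priority prevalence, the modality mix of the test dataset, normal
(low-priority) reports dominated by negated findings and stock normal
phrases, and abnormal (high-priority) reports carrying positive finding
language.  A small fraction of low-priority reports are "confusers" that
embed a benign risk statement containing high-salience disease terms
("... lifetime risk of developing breast cancer is 3.6%"), reproducing
the dominant false-positive mode of the original error analysis.  This
is an acknowledged emulation, not clinical language modeling.

Every report carries PHI-like planted tokens (dates, facility names,
record numbers) so the scrubber is exercised, and a small fraction omit
the IMPRESSION header to exercise the whole-body fallback path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus_io import ClinicalReport, Corpus, Label, Modality

__all__ = [
    "SyntheticCorpusSpec",
    "generate_corpus",
    "generate_training_pair",
    "TEST_SET_MODALITY_MIX",
    "TEST_SET_PREVALENCE",
]

#: Modality proportions of the 354-report test dataset
#: (35 mammograms, 36 CTs, 71 plain films, 70 ultrasounds, 142 MRIs).
TEST_SET_MODALITY_MIX: dict[Modality, float] = {
    Modality.mammogram: 35 / 354,
    Modality.ct: 36 / 354,
    Modality.plain_film: 71 / 354,
    Modality.ultrasound: 70 / 354,
    Modality.mri: 142 / 354,
}

#: High-priority prevalence of the test dataset (92 of 354 reports).
TEST_SET_PREVALENCE: float = 92 / 354

# Positive finding language for high-priority impressions.  Seeded from
# the clinical phrases the classifier is meant to key on (nodules,
# masses, infiltrates, actionable recommendations) and padded with
# plausible boilerplate.
FINDING_PHRASES: tuple[str, ...] = (
    "nodule identified",
    "possible developing mass",
    "small infiltrate suggesting early pneumonia",
    "right renal cyst requires 6 month follow up ultrasound",
    "lung nodule requires 4 month interval cat scan",
    "suspicious calcifications in the upper outer quadrant",
    "interval growth of the known lesion correlation recommended",
    "new compression deformity of the l1 vertebral body",
    "enlarging mass concerning for metastatic cancer",
    "acute appendicitis with periappendiceal inflammation",
    "findings suspicious for malignancy biopsy should be performed",
    "obstructing calculus with moderate hydronephrosis",
    "focal consolidation developing in the right lower lobe",
)

# Stock normal phrases (the common-phrase list's normal subset); these
# merge to single whitespace-free tokens during preprocessing.
NORMAL_PHRASES: tuple[str, ...] = (
    "no significant abnormality is identified",
    "no mammographic change or evidence of malignancy",
    "no acute cardiopulmonary process",
    "no acute pulmonary process",
    "within normal limits",
    "normal abdominal ultrasound",
    "no acute intracranial process",
    "appropriate for age",
    "routine annual screening mammogram",
    "no acute pathology",
)

# Negated-finding sentences; the negation scope remover deletes them
# entirely, so they contribute no features (normal reports collapse
# toward empty or phrase-only bags).
NEGATED_FINDINGS: tuple[str, ...] = (
    "no evidence of fracture",
    "no acute disease of the chest",
    "no focal consolidation pleural effusion or pneumothorax",
    "no suspicious mass or axillary lymphadenopathy",
    "no hydronephrosis or obstructing calculus",
    "without evidence of pneumonia",
    "no acute intracranial hemorrhage or mass effect",
)

# Benign risk statements for confuser reports.  Each embeds the
# recurring high-salience terms "developing ... cancer" inside varied
# statistical boilerplate; because the boilerplate wording differs
# between templates, a test-corpus confuser's benign vocabulary is
# usually out-of-vocabulary for the trained model while its disease
# terms are not — which is exactly what makes these reports the dominant
# false-positive source, as in the original error analysis.
BENIGN_RISK_TEMPLATES: tuple[str, ...] = (
    "negative according to the nci model the patients lifetime risk of developing breast cancer is {p}%",
    "per the gail model the estimated likelihood of developing breast cancer over a lifetime approaches {p}%",
    "tyrer cuzick assessment places the chance of developing cancer near {p}%",
    "population tables indicate baseline odds of developing cancer around {p}%",
    "screening guidance notes average propensity of developing cancer about {p}%",
    "actuarial figures quote cumulative frequency of developing cancer close to {p}%",
    "epidemiologic estimates give typical possibility of developing cancer roughly {p}%",
    "registry numbers show expected incidence of developing cancer under {p}%",
    "consensus literature cites mean probability of developing cancer below {p}%",
    "family history questionnaire suggests eventual prospect of developing cancer at {p}%",
)

_EXAM_PHRASES: dict[Modality, tuple[str, ...]] = {
    Modality.mammogram: ("bilateral screening mammogram",),
    Modality.ct: ("ct of the head", "ct of the abdomen and pelvis"),
    Modality.plain_film: (
        "chest radiograph two views",
        "plain film of the left wrist",
        "plain film of the abdomen",
    ),
    Modality.ultrasound: ("ultrasound of the abdomen", "renal ultrasound"),
    Modality.mri: (
        "mri of the brain",
        "mri of the cervical spine",
        "mri of the lumbar spine",
        "mri of the abdomen",
    ),
    Modality.other: ("diagnostic imaging study",),
}

_FACILITIES: tuple[str, ...] = (
    "MERCY HOSPITAL",
    "BLUE HILLS IMAGING CENTER",
    "ST VINCENT MEDICAL CENTER",
    "RIVERSIDE RADIOLOGY ASSOCIATES",
    "LAKESIDE COMMUNITY HOSPITAL",
    "GREENFIELD DIAGNOSTIC IMAGING",
)

_SIGNERS: tuple[str, ...] = ("DR SMITH", "DR JONES", "DR PATEL", "DR NGUYEN")

# Report-skeleton dialects.  The study practice received reports from
# three different hospital systems, so section labels and boilerplate
# wording vary between reports; this also keeps the whole-body fallback
# path (header omitted) from planting a large block of perfectly
# correlated boilerplate tokens in every headerless report.
_EXAM_LABELS: tuple[str, ...] = ("EXAM", "EXAMINATION", "STUDY")
_DATE_LINES: tuple[str, ...] = (
    "DATE OF SERVICE: {date}",
    "STUDY DATE: {date}",
    "EXAM DATE: {date}",
)
_ID_LINES: tuple[str, ...] = (
    "MRN: {mrn}",
    "MEDICAL RECORD NUMBER: {mrn}",
    "ACCESSION: {mrn}",
)
_COMPARISON_LINES: tuple[str, ...] = (
    "COMPARISON: prior examination from {facility}",
    "COMPARISON: none available",
    "CLINICAL HISTORY: referred by {facility}",
)
_TECHNIQUE_LINES: tuple[str, ...] = (
    "TECHNIQUE: standard departmental protocol",
    "TECHNIQUE: multiplanar images acquired per routine",
    "TECHNIQUE: standard views were obtained",
)
_SIGNED_LINES: tuple[str, ...] = (
    "SIGNED: {signer} {date}",
    "ELECTRONICALLY SIGNED: {signer} {date}",
    "DICTATED BY: {signer} {date}",
)


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Parameters controlling corpus generation.

    Defaults reproduce the structure of the study's 354-report test set;
    ``generate_training_pair`` overrides size and prevalence for the
    100-report balanced training corpus.
    """

    n_reports: int = 354
    prevalence_high: float = TEST_SET_PREVALENCE
    modality_mix: Mapping[Modality, float] = field(
        default_factory=lambda: dict(TEST_SET_MODALITY_MIX)
    )
    confuser_rate: float = 0.05
    negation_rate: float = 0.8
    header_omission_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 2:
            raise ValueError("n_reports must be >= 2")
        total = sum(self.modality_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"modality_mix must sum to 1 (got {total})")
        for name in ("prevalence_high", "confuser_rate", "negation_rate", "header_omission_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


def _class_counts(spec: SyntheticCorpusSpec) -> tuple[int, int]:
    n_high = round(spec.prevalence_high * spec.n_reports)
    n_low = spec.n_reports - n_high
    if n_high == 0 or n_low == 0:
        raise ValueError(
            f"infeasible spec: prevalence {spec.prevalence_high} over "
            f"{spec.n_reports} reports rounds to {n_high} high / {n_low} low; "
            "both classes must be non-empty"
        )
    return n_high, n_low


def _modality_counts(spec: SyntheticCorpusSpec) -> dict[Modality, int]:
    """Largest-remainder apportionment of n_reports over the mix."""
    quotas = {m: spec.n_reports * frac for m, frac in spec.modality_mix.items()}
    counts = {m: int(np.floor(q)) for m, q in quotas.items()}
    short = spec.n_reports - sum(counts.values())
    by_remainder = sorted(
        quotas, key=lambda m: (-(quotas[m] - counts[m]), m.value)
    )
    for m in by_remainder[:short]:
        counts[m] += 1
    return counts


def _random_date(rng: np.random.Generator) -> str:
    year = int(rng.integers(2011, 2014))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    return f"{month:02d}/{day:02d}/{year}"


def _sentences(parts: list[str]) -> str:
    return ". ".join(p[:1].upper() + p[1:] for p in parts) + "."


def _low_impression(spec: SyntheticCorpusSpec, rng: np.random.Generator, confuser: bool) -> str:
    parts: list[str] = []
    if confuser:
        template = str(rng.choice(BENIGN_RISK_TEMPLATES))
        pct = f"{rng.uniform(1.0, 15.0):.1f}"
        parts.append(template.format(p=pct))
        if rng.random() < spec.negation_rate:
            parts.append(str(rng.choice(NEGATED_FINDINGS)))
    else:
        k = int(rng.integers(1, 3))
        parts.extend(rng.choice(NORMAL_PHRASES, size=k, replace=False))
        if rng.random() < spec.negation_rate:
            j = int(rng.integers(1, 3))
            parts.extend(rng.choice(NEGATED_FINDINGS, size=j, replace=False))
    order = rng.permutation(len(parts))
    return _sentences([parts[i] for i in order])


def _high_impression(rng: np.random.Generator) -> str:
    k = int(rng.integers(1, 4))
    parts = list(rng.choice(FINDING_PHRASES, size=k, replace=False))
    return _sentences(parts)


def _report_text(
    spec: SyntheticCorpusSpec,
    rng: np.random.Generator,
    modality: Modality,
    label: Label,
    confuser: bool,
    omit_header: bool,
) -> str:
    exam = str(rng.choice(_EXAM_PHRASES[modality]))
    facility = str(rng.choice(_FACILITIES))
    signer = str(rng.choice(_SIGNERS))
    date = _random_date(rng)
    mrn = f"{int(rng.integers(10_000_000, 100_000_000))}"
    if label is Label.high:
        impression = _high_impression(rng)
        findings = _sentences([str(rng.choice(FINDING_PHRASES))])
    else:
        impression = _low_impression(spec, rng, confuser)
        findings = _sentences([str(rng.choice(NEGATED_FINDINGS))])
    lines = [
        f"{rng.choice(_EXAM_LABELS)}: {exam}",
        str(rng.choice(_DATE_LINES)).format(date=date),
        str(rng.choice(_ID_LINES)).format(mrn=mrn),
        str(rng.choice(_COMPARISON_LINES)).format(facility=facility),
        str(rng.choice(_TECHNIQUE_LINES)),
        f"FINDINGS: {findings}",
    ]
    if omit_header:
        lines.append(impression)
    else:
        lines.append(f"IMPRESSION: {impression}")
    lines.append(str(rng.choice(_SIGNED_LINES)).format(signer=signer, date=date))
    return "\n".join(lines)


def generate_corpus(
    spec: SyntheticCorpusSpec, return_metadata: bool = False
) -> Corpus | tuple[Corpus, dict[str, dict[str, bool]]]:
    """Generate a fully labeled corpus, deterministically given the seed.

    With ``return_metadata=True`` also returns, per report_id, whether
    the report was generated as a confuser and whether its IMPRESSION
    header was omitted (useful for error-mode analysis in tests).
    """
    n_high, n_low = _class_counts(spec)
    mod_counts = _modality_counts(spec)
    rng = np.random.default_rng(spec.seed)

    labels = np.array([Label.high] * n_high + [Label.low] * n_low, dtype=object)
    rng.shuffle(labels)
    modalities = np.array(
        [m for m in sorted(mod_counts, key=lambda m: m.value) for _ in range(mod_counts[m])],
        dtype=object,
    )
    rng.shuffle(modalities)

    width = len(str(spec.n_reports))
    reports: list[ClinicalReport] = []
    metadata: dict[str, dict[str, bool]] = {}
    for i in range(spec.n_reports):
        rid = f"R{i + 1:0{width}d}"
        label = labels[i]
        confuser = bool(label is Label.low and rng.random() < spec.confuser_rate)
        omit_header = bool(rng.random() < spec.header_omission_rate)
        text = _report_text(spec, rng, modalities[i], label, confuser, omit_header)
        reports.append(
            ClinicalReport(report_id=rid, raw_text=text, modality=modalities[i], label=label)
        )
        metadata[rid] = {"confuser": confuser, "header_omitted": omit_header}

    corpus = Corpus(reports=reports, name=f"synthetic-n{spec.n_reports}-seed{spec.seed}")
    if return_metadata:
        return corpus, metadata
    return corpus


def generate_training_pair(seed: int = 0) -> Corpus:
    """A balanced 100-report training corpus (50 high / 50 low)."""
    spec = SyntheticCorpusSpec(n_reports=100, prevalence_high=0.5, seed=seed)
    return generate_corpus(spec)
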