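"""Registry of the 15 patient-derived cancer model (PDCM) entity types.

The type set mirrors the most commonly curated attributes of the
CancerModels.Org data model: what was diagnosed, what kind of model was
derived, how it was characterized molecularly, what treatments were tested,
and so on.  Each entry carries a short working definition and example
surface forms that double as the seed lexicon for synthetic corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class EntityType:
    """One annotatable concept, e.g. ``biomarker`` or ``host_strain``.

    ``name`` must be a lowercase identifier usable as an inline XML-style
    tag (``<biomarker>...</biomarker>``).
    """

    name: str
    definition: str
    examples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name or not self.name.replace("_", "a").isalnum() or not self.name.islower():
            raise ValueError(f"entity type name must be a lowercase identifier: {self.name!r}")


DEFAULT_TYPES: tuple[EntityType, ...] = (
    EntityType(
        "diagnosis",
        "Diagnosis of the patient tumor from which the cancer model was derived",
        ("TNBC", "Ewing sarcoma", "lung adenocarcinoma", "glioblastoma"),
    ),
    EntityType(
        "age_category",
        "Age category of the patient at tissue sampling",
        ("adult", "pediatric"),
    ),
    EntityType(
        "genetic_effect",
        "Chromosomal rearrangement or gene-level change",
        ("missense", "amplification", "deletion", "fusion"),
    ),
    EntityType(
        "model_type",
        "Kind of patient-derived model",
        ("PDX", "organoid", "cell line"),
    ),
    EntityType(
        "molecular_char",
        "Assay or data modality generated from the model",
        ("RNA sequencing", "whole-exome sequencing", "immunohistochemistry"),
    ),
    EntityType(
        "biomarker",
        "Gene, protein or molecule identified in or associated with the tumor",
        ("BRCA1", "IDH", "KRAS", "ALK", "PTEN"),
    ),
    EntityType(
        "treatment",
        "Treatment received by the patient or tested on the model",
        ("surgery", "chemotherapy", "PARP-inhibitor", "cisplatin"),
    ),
    EntityType(
        "response_to_treatment",
        "Effect of a treatment on the tumor or model",
        ("progression-free survival", "reduced tumor growth", "partial response"),
    ),
    EntityType(
        "sample_type",
        "Material used to generate the model or how it was obtained",
        ("tissue fragment", "autopsy", "biopsy"),
    ),
    EntityType(
        "tumor_type",
        "Collected tumor type used for generating the model",
        ("primary", "recurrent", "metastatic"),
    ),
    EntityType(
        "cancer_grade",
        "Grade reflecting how quickly the cancer is likely to grow",
        ("grade 1", "low-grade", "high-grade"),
    ),
    EntityType(
        "cancer_stage",
        "Extent of the cancer per a staging system",
        ("TNM system", "T0", "stage I"),
    ),
    EntityType(
        "clinical_trial",
        "Clinical trial type or identifier",
        ("phase II", "prospective randomized clinical trials", "NCT02720029"),
    ),
    EntityType(
        "host_strain",
        "Mouse host strain engrafted to generate a PDX model",
        ("NOD-SCID", "NSG", "nude mice"),
    ),
    EntityType(
        "model_id",
        "Identifier of the cancer model generated in the study",
        ("PHLC402", "CTG-0166"),
    ),
)

DEFAULT_TYPE_NAMES: tuple[str, ...] = tuple(t.name for t in DEFAULT_TYPES)

# Per-type mention counts (train, dev, test) of the released 100-abstract
# gold corpus.  These drive the default frequency profile of the synthetic
# generator -- heavily skewed, with biomarker/treatment/diagnosis frequent
# and cancer_grade/cancer_stage rare -- and are the reference for corpus
# bookkeeping checks.
REFERENCE_SPLIT_COUNTS: dict[str, tuple[int, int, int]] = {
    "diagnosis": (362, 122, 114),
    "age_category": (19, 0, 0),
    "genetic_effect": (69, 20, 33),
    "model_type": (326, 114, 110),
    "molecular_char": (128, 37, 46),
    "biomarker": (503, 118, 163),
    "treatment": (426, 77, 130),
    "response_to_treatment": (99, 21, 28),
    "sample_type": (22, 8, 7),
    "tumor_type": (61, 19, 28),
    "cancer_grade": (6, 1, 1),
    "cancer_stage": (7, 1, 4),
    "clinical_trial": (35, 2, 4),
    "host_strain": (9, 0, 7),
    "model_id": (17, 2, 7),
}

REFERENCE_TOTALS: dict[str, int] = {
    name: sum(cells) for name, cells in REFERENCE_SPLIT_COUNTS.items()
}


def registry_index(name: str) -> int:
    """Position of a type in the default registry (used for tie-breaks)."""
    try:
        return DEFAULT_TYPE_NAMES.index(name)
    except ValueError:
        return len(DEFAULT_TYPE_NAMES)


def get_type(name: str) -> EntityType:
    for t in DEFAULT_TYPES:
        if t.name == name:
            return t
    raise KeyError(name)
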