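"""Feature vectors for single-disease and disease-pair imputation.

A single-disease record is described by its Analysis-B prevalence curve (66
normalized counts plus 66 cumulative counts), its embedding vector, a
biological-system category one-hot (20 systems plus "Other"), three scalar
descriptors (sex bias, mean carrier age, onset age), and study descriptors
(data type, mathematical model, cohort sex and country as one-hots).

A disease-pair record replaces the three continuous blocks by their pairwise
mean and absolute difference — the difference captures disease-disease
dissimilarity — plus supplemental scalars (same-category indicator, absolute
deltas of sex bias, mean age, onset age) and the same study descriptors.
Absolute differences keep pair features invariant to pair ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .archetypes import N_AGES
from .vocab import CATEGORIES, DATA_TYPES, MODELS

UNKNOWN = "unknown"


class SchemaError(ValueError):
    """A categorical label falls outside its fixed vocabulary."""


def cumulative_counts(normalized: np.ndarray) -> np.ndarray:
    """Running sum of a normalized 66-bin curve; final element is 1."""
    v = np.asarray(normalized, dtype=float)
    if v.shape != (N_AGES,):
        raise ValueError(f"expected a {N_AGES}-vector")
    if not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise ValueError("input must be normalized to sum to 1")
    return np.cumsum(v)


def _one_hot(label, vocab, fieldname, allow_unknown=False) -> np.ndarray:
    labels = list(vocab)
    if label not in labels:
        if allow_unknown and UNKNOWN in labels:
            label = UNKNOWN
        else:
            raise SchemaError(f"unknown {fieldname} label: {label!r}")
    out = np.zeros(len(labels))
    out[labels.index(label)] = 1.0
    return out


@dataclass
class SingleDiseaseInputs:
    """The per-disease ingredients of a feature vector."""

    curve: np.ndarray
    embedding: np.ndarray
    category: str
    sex_bias: float
    mean_carrier_age: float
    onset_age: float


@dataclass
class FeatureSchema:
    """Ordered feature blocks with lengths, offsets and group tags."""

    blocks: list  # (name, length, group)
    vocabularies: dict

    @property
    def length(self) -> int:
        return sum(b[1] for b in self.blocks)

    def slices(self) -> dict:
        out, off = {}, 0
        for name, n, _ in self.blocks:
            out[name] = slice(off, off + n)
            off += n
        return out

    def groups(self) -> dict:
        """Map group tag -> column index array (for importance aggregation)."""
        out = {}
        for (name, n, group), sl in zip(self.blocks, self.slices().values()):
            out.setdefault(group, []).extend(range(sl.start, sl.stop))
        return {g: np.array(ix) for g, ix in out.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "blocks": [list(b) for b in self.blocks],
                "vocabularies": {k: list(v) for k, v in self.vocabularies.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        obj = json.loads(text)
        return cls(
            blocks=[tuple(b) for b in obj["blocks"]],
            vocabularies={k: tuple(v) for k, v in obj["vocabularies"].items()},
        )


class FeatureBuilder:
    """Assembles fixed-order feature vectors and their schema.

    Sex and country vocabularies are taken from the observed estimate table
    plus a reserved "unknown" level; category, data type and model labels
    are fixed vocabularies and unknown labels raise :class:`SchemaError`.
    """

    def __init__(self, sexes=("M", "F"), countries=("US",), embedding_dim: int = 20):
        self.sexes = tuple(dict.fromkeys(list(sexes) + [UNKNOWN]))
        self.countries = tuple(dict.fromkeys(list(countries) + [UNKNOWN]))
        self.dim = embedding_dim
        self.vocabularies = {
            "category": CATEGORIES,
            "data_type": DATA_TYPES,
            "model": MODELS,
            "sex": self.sexes,
            "country": self.countries,
        }

    # -- schemas -----------------------------------------------------------
    @property
    def single_schema(self) -> FeatureSchema:
        blocks = [
            ("normalized_counts", N_AGES, "curve"),
            ("cumulative_counts", N_AGES, "curve"),
            ("embedding", self.dim, "embedding"),
            ("category", len(CATEGORIES), "other"),
            ("sex_bias", 1, "other"),
            ("mean_carrier_age", 1, "other"),
            ("onset_age", 1, "other"),
            ("data_type", len(DATA_TYPES), "data_type"),
            ("model", len(MODELS), "model"),
            ("sex", len(self.sexes), "other"),
            ("country", len(self.countries), "country"),
        ]
        return FeatureSchema(blocks, self.vocabularies)

    @property
    def pair_schema(self) -> FeatureSchema:
        blocks = [
            ("mean_normalized_counts", N_AGES, "curve"),
            ("diff_normalized_counts", N_AGES, "curve"),
            ("mean_cumulative_counts", N_AGES, "curve"),
            ("diff_cumulative_counts", N_AGES, "curve"),
            ("mean_embedding", self.dim, "embedding"),
            ("diff_embedding", self.dim, "embedding"),
            ("same_category", 1, "other"),
            ("abs_diff_sex_bias", 1, "other"),
            ("abs_diff_mean_carrier_age", 1, "other"),
            ("abs_diff_onset_age", 1, "other"),
            ("data_type", len(DATA_TYPES), "data_type"),
            ("model", len(MODELS), "model"),
            ("sex", len(self.sexes), "other"),
            ("country", len(self.countries), "country"),
        ]
        return FeatureSchema(blocks, self.vocabularies)

    # -- builders ----------------------------------------------------------
    def _continuous(self, d: SingleDiseaseInputs):
        curve = np.asarray(d.curve, float)
        emb = np.asarray(d.embedding, float)
        if emb.shape != (self.dim,):
            raise SchemaError(f"embedding must have length {self.dim}")
        return curve, cumulative_counts(curve), emb

    def build_single(
        self, d: SingleDiseaseInputs, data_type: str, model: str, sex: str, country: str
    ) -> np.ndarray:
        curve, cum, emb = self._continuous(d)
        parts = [
            curve,
            cum,
            emb,
            _one_hot(d.category, CATEGORIES, "category"),
            [d.sex_bias, d.mean_carrier_age, d.onset_age],
            _one_hot(data_type, DATA_TYPES, "data_type"),
            _one_hot(model, MODELS, "model"),
            _one_hot(sex, self.sexes, "sex", allow_unknown=True),
            _one_hot(country, self.countries, "country", allow_unknown=True),
        ]
        vec = np.concatenate([np.asarray(p, float).ravel() for p in parts])
        assert len(vec) == self.single_schema.length
        return vec

    def build_pair(
        self,
        a: SingleDiseaseInputs,
        b: SingleDiseaseInputs,
        data_type: str,
        model: str,
        sex: str,
        country: str,
    ) -> np.ndarray:
        ca, cca, ea = self._continuous(a)
        cb, ccb, eb = self._continuous(b)
        parts = [
            0.5 * (ca + cb),
            np.abs(ca - cb),
            0.5 * (cca + ccb),
            np.abs(cca - ccb),
            0.5 * (ea + eb),
            np.abs(ea - eb),
            [
                1.0 if a.category == b.category else 0.0,
                abs(a.sex_bias - b.sex_bias),
                abs(a.mean_carrier_age - b.mean_carrier_age),
                abs(a.onset_age - b.onset_age),
            ],
            _one_hot(data_type, DATA_TYPES, "data_type"),
            _one_hot(model, MODELS, "model"),
            _one_hot(sex, self.sexes, "sex", allow_unknown=True),
            _one_hot(country, self.countries, "country", allow_unknown=True),
        ]
        vec = np.concatenate([np.asarray(p, float).ravel() for p in parts])
        assert len(vec) == self.pair_schema.length
        return vec
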