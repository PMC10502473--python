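"""Declarative signature definitions and their on-disk registry format.

A signature registry is a YAML (or JSON) document with a top-level
``signatures:`` list. Each entry carries a ``scheme`` tag that selects the
scoring rule, plus whatever scheme-specific content the rule needs (weights,
normalization genes, centroid profiles, clipping boundaries). Published
signatures reference external publications whose gene lists, weights and
centroids are supplied by the user as registry content; nothing is embedded
in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

SCHEMES = frozenset(
    {
        "mean_centered",
        "weighted_normalized",
        "nearest_centroid",
        "negated_sum",
        "median_log2",
        "single_gene",
        "first_pc",
        "enrichment",
        "linear_weighted",
    }
)


@dataclass
class SignatureDefinition:
    """One transcriptional signature: a scheme tag plus its gene content.

    Parameters
    ----------
    name : str
        Unique signature name; becomes the score column name.
    scheme : str
        One of :data:`SCHEMES`.
    genes : list of str
        Signature gene identifiers (duplicate-free, non-empty).
    weights : list of float, optional
        Per-gene weights, aligned 1:1 with ``genes`` (weighted_normalized,
        linear_weighted).
    bias : float
        Additive constant for weighted schemes.
    normalization_genes : list of str, optional
        Reference genes whose geometric mean normalizes the signature genes
        (weighted_normalized).
    centroids : dict, optional
        label -> {gene -> value} profiles (nearest_centroid).
    boundaries : (float, float), optional
        Clipping bounds applied to per-gene centred values
        (weighted_normalized).
    threshold : float, optional
        Decision cut for dichotomising a continuous score; scores are kept
        continuous, the threshold is carried for downstream use.
    input_scale : str
        "log2" (default) or "fpkm"; linear_weighted signatures such as DDIR
        operate on the linear FPKM scale.
    exclude_from_average : bool
        For enrichment signatures: exclude this cell type (e.g. fibroblasts)
        from the average enrichment score.
    """

    name: str
    scheme: str
    genes: list[str]
    weights: list[float] | None = None
    bias: float = 0.0
    normalization_genes: list[str] | None = None
    centroids: dict[str, dict[str, float]] | None = None
    boundaries: tuple[float, float] | None = None
    threshold: float | None = None
    input_scale: str = "log2"
    exclude_from_average: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(
                f"signature {self.name!r}: unknown scheme {self.scheme!r}; "
                f"expected one of {sorted(SCHEMES)}"
            )
        if not self.genes:
            raise ValueError(f"signature {self.name!r}: empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r}: duplicate genes")
        if self.scheme == "single_gene" and len(self.genes) != 1:
            raise ValueError(
                f"signature {self.name!r}: single_gene scheme needs exactly one gene"
            )
        if self.scheme in ("weighted_normalized", "linear_weighted"):
            if self.weights is None or len(self.weights) != len(self.genes):
                raise ValueError(
                    f"signature {self.name!r}: scheme {self.scheme} requires "
                    "weights aligned 1:1 with genes"
                )
        if self.scheme == "weighted_normalized" and not self.normalization_genes:
            raise ValueError(
                f"signature {self.name!r}: weighted_normalized requires "
                "non-empty normalization_genes"
            )
        if self.scheme == "nearest_centroid":
            if not self.centroids or len(self.centroids) < 2:
                raise ValueError(
                    f"signature {self.name!r}: nearest_centroid requires >=2 centroids"
                )
        if self.boundaries is not None:
            lo, hi = self.boundaries
            if not lo < hi:
                raise ValueError(f"signature {self.name!r}: boundaries must satisfy lo < hi")
            self.boundaries = (float(lo), float(hi))
        if self.input_scale not in ("log2", "fpkm"):
            raise ValueError(f"signature {self.name!r}: input_scale must be 'log2' or 'fpkm'")

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "scheme": self.scheme, "genes": list(self.genes)}
        if self.weights is not None:
            d["weights"] = [float(w) for w in self.weights]
        if self.bias:
            d["bias"] = float(self.bias)
        if self.normalization_genes is not None:
            d["normalization_genes"] = list(self.normalization_genes)
        if self.centroids is not None:
            d["centroids"] = {
                k: {g: float(v) for g, v in prof.items()} for k, prof in self.centroids.items()
            }
        if self.boundaries is not None:
            d["boundaries"] = [float(self.boundaries[0]), float(self.boundaries[1])]
        if self.threshold is not None:
            d["threshold"] = float(self.threshold)
        if self.input_scale != "log2":
            d["input_scale"] = self.input_scale
        if self.exclude_from_average:
            d["exclude_from_average"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureDefinition":
        d = dict(d)
        if "boundaries" in d and d["boundaries"] is not None:
            d["boundaries"] = tuple(d["boundaries"])
        return cls(**d)


def load_registry(path) -> list[SignatureDefinition]:
    """Read a signature registry file (YAML/JSON dialect).

    Raises ``ValueError`` on duplicate signature names or malformed entries.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "signatures" not in doc:
        raise ValueError(f"{path}: registry file must contain a top-level 'signatures' list")
    sigs = [SignatureDefinition.from_dict(entry) for entry in doc["signatures"]]
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate signature names {dupes}")
    return sigs


def save_registry(signatures: list[SignatureDefinition], path) -> None:
    """Write signatures to a YAML registry file."""
    doc = {"signatures": [s.to_dict() for s in signatures]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
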