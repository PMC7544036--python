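"""IRGP signatures: ordered gene pairs with Cox coefficients.

A signature defines the risk score r(sample) = sum_k beta_k * s_k(sample),
where s_k is the binary within-sample indicator of pair k (1 iff the first
gene's expression strictly exceeds the second's). Because the score depends
on expression only through within-sample orderings, it transfers across
platforms without normalization.

The package bundles a published reference signature for melanoma overall
survival (33 pairs over 52 immune genes, companion cutoff -1.130), loadable
with :func:`load_melanoma_signature`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import yaml

from .io import canonicalize_symbol

__all__ = ["GenePair", "Signature", "load_melanoma_signature", "read_signature", "write_signature"]


@dataclass(frozen=True, order=True)
class GenePair:
    """An ordered pair of gene symbols; (A, B) is distinct from (B, A)."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_a", canonicalize_symbol(self.gene_a))
        object.__setattr__(self, "gene_b", canonicalize_symbol(self.gene_b))
        if self.gene_a == self.gene_b:
            raise ValueError(f"gene pair must involve two distinct genes, got {self.gene_a!r} twice")

    @property
    def pair_id(self) -> str:
        return f"{self.gene_a}__{self.gene_b}"

    @classmethod
    def from_id(cls, pair_id: str) -> "GenePair":
        gene_a, gene_b = pair_id.split("__")
        return cls(gene_a, gene_b)

    def reversed(self) -> "GenePair":
        return GenePair(self.gene_b, self.gene_a)


@dataclass
class Signature:
    """Ordered (pair, coefficient) entries with an optional score cutoff."""

    entries: list[tuple[GenePair, float]]
    cutoff: float | None = None
    name: str = "signature"
    note: str = ""

    def __post_init__(self) -> None:
        pairs = [pair for pair, _ in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pairs in signature")
        for pair, coef in self.entries:
            if not math.isfinite(coef) or coef == 0:
                raise ValueError(f"coefficient for {pair.pair_id} must be finite and nonzero, got {coef}")

    @property
    def pairs(self) -> list[GenePair]:
        return [pair for pair, _ in self.entries]

    @property
    def coefficients(self) -> list[float]:
        return [coef for _, coef in self.entries]

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in (pair.gene_a, pair.gene_b)}

    def __len__(self) -> int:
        return len(self.entries)

    def to_dict(self) -> dict:
        payload = {
            "name": self.name,
            "note": self.note,
            "entries": [
                {"gene_a": p.gene_a, "gene_b": p.gene_b, "coefficient": c} for p, c in self.entries
            ],
        }
        if self.cutoff is not None:
            payload["cutoff"] = self.cutoff
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "Signature":
        entries = [
            (GenePair(e["gene_a"], e["gene_b"]), float(e["coefficient"])) for e in payload["entries"]
        ]
        cutoff = payload.get("cutoff")
        return cls(
            entries=entries,
            cutoff=None if cutoff is None else float(cutoff),
            name=payload.get("name", "signature"),
            note=payload.get("note", ""),
        )



def read_signature(path: str) -> Signature:
    """Read a signature from JSON or YAML (extension-detected)."""
    with open(path) as handle:
        text = handle.read()
    payload = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    return Signature.from_dict(payload)


def write_signature(signature: Signature, path: str) -> None:
    with open(path, "w") as handle:
        if str(path).endswith((".yaml", ".yml")):
            yaml.safe_dump(signature.to_dict(), handle, sort_keys=False)
        else:
            json.dump(signature.to_dict(), handle, indent=2)
            handle.write("\n")


def load_melanoma_signature() -> Signature:
    """The bundled 33-pair melanoma IRGP signature with cutoff -1.130."""
    text = resources.files("irgps.data").joinpath("melanoma_irgps_signature.json").read_text()
    return Signature.from_dict(json.loads(text))
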