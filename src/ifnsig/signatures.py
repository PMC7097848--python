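"""Built-in composite gene signatures.

The package ships two five-gene blood signatures as data:

* ``ifn`` — type I interferon response: PLSCR1, OASL, IFI6, IFIT3, IFITM3.
* ``il36`` — IL-36 activity: IL1B, PI3, VNN2, TNFAIP6, SERPINB1.

Both are scored as the per-sample median of calibrator-normalized
expression (see :mod:`ifnsig.scoring`).
"""

from __future__ import annotations

from importlib import resources

from .containers import GeneSignature

__all__ = ["default_signature", "available_signatures", "IFN_GENES", "IL36_GENES"]

IFN_GENES = ("PLSCR1", "OASL", "IFI6", "IFIT3", "IFITM3")
IL36_GENES = ("IL1B", "PI3", "VNN2", "TNFAIP6", "SERPINB1")

_ORDER: dict[str, tuple[str, ...]] = {"ifn": IFN_GENES, "il36": IL36_GENES}


def _load() -> dict[str, GeneSignature]:
    # GMT lines carry the signature genes; the canonical order comes from
    # _ORDER because GMT semantics are set-valued.
    from .io import read_gmt

    path = resources.files("ifnsig") / "data" / "signatures.gmt"
    with resources.as_file(path) as p:
        library = read_gmt(p)
    out: dict[str, GeneSignature] = {}
    for name, genes in library.items():
        order = _ORDER.get(name)
        ordered = order if order and set(order) == set(genes) else tuple(sorted(genes))
        out[name] = GeneSignature(name=name, genes=ordered)
    return out


def available_signatures() -> list[str]:
    return sorted(_load())


def default_signature(name: str) -> GeneSignature:
    """Return a built-in signature by name (``"ifn"`` or ``"il36"``)."""
    sigs = _load()
    try:
        return sigs[name]
    except KeyError:
        raise KeyError(
            f"unknown signature {name!r}; available: {sorted(sigs)}"
        ) from None
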