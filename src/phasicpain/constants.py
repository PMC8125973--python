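"""Canonical orderings shared across the pipeline.

The AU list and its order are frozen so that feature-vector layouts and
CSV column orders are stable across runs and versions.
"""

#: The 17 facial action units whose continuous intensities (OpenFace ``AU*_r``
#: outputs) form one sample's multivariate time series, in canonical order.
AU_NAMES: tuple[str, ...] = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10",
    "AU12", "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26", "AU45",
)

N_AUS = len(AU_NAMES)

#: OpenFace intensity column name for each canonical AU.
AU_COLUMNS: tuple[str, ...] = tuple(f"{au}_r" for au in AU_NAMES)

#: The seven stimulus classes: baseline plus heat/electrical at three
#: calibrated intensities.  The order defines class indices 0..6 everywhere.
CLASSES: tuple[str, ...] = ("B", "H1", "H2", "H3", "E1", "E2", "E3")

CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

#: Stimulus modalities in the order used by the multi-task modality head.
MODALITIES: tuple[str, ...] = ("B", "H", "E")

#: AUs that carry the pain response in the synthetic generator: brow lowerer,
#: cheek raiser, lid tightener, nose wrinkler, upper-lip raiser and eye
#: closure — the core of prototypical facial pain expressions.
PAIN_AUS: tuple[str, ...] = ("AU04", "AU06", "AU07", "AU09", "AU10", "AU45")


def class_of(modality: str, intensity: int) -> str:
    """Map a (modality, intensity) pair to its class code; intensity 0 is B."""
    if intensity == 0:
        return "B"
    if modality not in ("H", "E"):
        raise ValueError(f"painful stimulus needs modality H or E, got {modality!r}")
    return f"{modality}{intensity}"


def split_class(code: str) -> tuple[str, int]:
    """Inverse of :func:`class_of`: class code -> (modality, intensity)."""
    if code == "B":
        return "B", 0
    if code in CLASS_TO_INDEX:
        return code[0], int(code[1])
    raise ValueError(f"unknown class code {code!r}")
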