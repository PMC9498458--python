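"""Published reference values for moth mitogenome composition.

``MOTH_COMPOSITION_REFERENCE`` holds whole-mitogenome nucleotide
compositions reported for nineteen moth species across six families
(Drepanidae, Erebidae, Geometridae, Noctuidae, Notodontidae, Sphingidae).
It is used as a regression fixture: for every row the printed A% + T% must
reproduce the printed AT% (and C% + G% the printed GC%) to the reporting
precision, which pins down the package's compositional arithmetic and
rounding conventions against published practice.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CompositionRow", "MOTH_COMPOSITION_REFERENCE"]


@dataclass(frozen=True)
class CompositionRow:
    family: str
    species: str
    length_bp: int
    a_pct: float
    t_pct: float
    c_pct: float
    g_pct: float
    at_pct: float
    gc_pct: float


MOTH_COMPOSITION_REFERENCE: tuple[CompositionRow, ...] = (
    CompositionRow("Drepanidae", "Auzata chinensis", 15243, 41.1, 39.2, 11.60, 8.20, 80.30, 19.80),
    CompositionRow("Drepanidae", "Cyclidia fractifasciata", 15177, 39.8, 40.8, 11.90, 7.50, 80.60, 19.40),
    CompositionRow("Erebidae", "Barsine fuscozonata", 15391, 40.2, 41.7, 10.70, 7.40, 81.90, 18.10),
    CompositionRow("Erebidae", "Ericeia subcinerea", 15586, 39.9, 40.3, 12.40, 7.50, 80.20, 19.90),
    CompositionRow("Erebidae", "Vamuna remelana", 15424, 40.2, 40.2, 12.10, 7.50, 80.40, 19.60),
    CompositionRow("Geometridae", "Medasina albidaria", 15504, 41.4, 39.8, 10.90, 7.90, 81.20, 18.80),
    CompositionRow("Geometridae", "Mesastrape fulguraria", 15561, 41.7, 39.4, 11.40, 7.40, 81.10, 18.80),
    CompositionRow("Geometridae", "Metabraxas rubrotincta", 15577, 41.9, 39.5, 11.20, 7.50, 81.40, 18.70),
    CompositionRow("Geometridae", "Obeidia gigantearia", 15429, 41.2, 39.9, 11.20, 7.70, 81.10, 18.90),
    CompositionRow("Geometridae", "Ophthalmitis albosignaria", 15749, 42.1, 39.8, 10.70, 7.40, 81.90, 18.10),
    CompositionRow("Geometridae", "Ourapteryx ebuleata", 15667, 41.0, 39.5, 11.70, 7.80, 80.50, 19.50),
    CompositionRow("Noctuidae", "Cymatophoropsis trimaculata", 15369, 40.1, 40.3, 11.80, 7.70, 80.40, 19.50),
    CompositionRow("Notodontidae", "Epodonta lineata", 15358, 40.7, 39.3, 12.20, 7.70, 80.00, 19.90),
    CompositionRow("Notodontidae", "Kamalia tattakana", 15381, 40.7, 37.4, 13.80, 8.10, 78.10, 21.90),
    CompositionRow("Notodontidae", "Spatalia doerriesi", 15475, 39.2, 39.7, 13.50, 7.70, 78.90, 21.20),
    CompositionRow("Notodontidae", "Zaranga tukuringra", 15249, 41.1, 37.5, 13.60, 7.90, 78.60, 21.50),
    CompositionRow("Sphingidae", "Acosmeryx castanea", 15201, 41.0, 39.6, 11.80, 7.60, 80.60, 19.40),
    CompositionRow("Sphingidae", "Marumba cristata", 15744, 40.5, 41.1, 11.10, 7.30, 81.60, 18.40),
    CompositionRow("Sphingidae", "Rhagastis castor", 15265, 41.1, 39.2, 12.30, 7.50, 80.30, 19.80),
)
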