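"""Canonical country vocabulary and alias table for affiliation parsing.

The canonical names follow Scopus usage (English short names). The alias
table maps common variant spellings, endonyms and abbreviations onto the
canonical name; it can be extended at run time via the ingest config.
"""

CANONICAL_COUNTRIES = frozenset(
    {
        "Argentina", "Australia", "Austria", "Bangladesh", "Belgium",
        "Brazil", "Bulgaria", "Canada", "Chile", "China", "Colombia",
        "Croatia", "Cuba", "Czech Republic", "Denmark", "Egypt", "Estonia",
        "Finland", "France", "Germany", "Greece", "Hong Kong", "Hungary",
        "Iceland", "India", "Indonesia", "Iran", "Ireland", "Israel",
        "Italy", "Japan", "Jordan", "Kenya", "Kuwait", "Latvia", "Lebanon",
        "Lithuania", "Luxembourg", "Malaysia", "Mexico", "Morocco",
        "Netherlands", "New Zealand", "Nigeria", "Norway", "Pakistan",
        "Peru", "Philippines", "Poland", "Portugal", "Qatar", "Romania",
        "Russia", "Saudi Arabia", "Serbia", "Singapore", "Slovakia",
        "Slovenia", "South Africa", "South Korea", "Spain", "Sri Lanka",
        "Sweden", "Switzerland", "Taiwan", "Thailand", "Tunisia", "Turkey",
        "Ukraine", "United Arab Emirates", "United Kingdom", "United States",
        "Uruguay", "Venezuela", "Vietnam",
    }
)

COUNTRY_ALIASES = {
    "brasil": "Brazil",
    "usa": "United States",
    "u.s.a.": "United States",
    "united states of america": "United States",
    "uk": "United Kingdom",
    "u.k.": "United Kingdom",
    "england": "United Kingdom",
    "scotland": "United Kingdom",
    "wales": "United Kingdom",
    "northern ireland": "United Kingdom",
    "great britain": "United Kingdom",
    "republic of korea": "South Korea",
    "korea": "South Korea",
    "russian federation": "Russia",
    "viet nam": "Vietnam",
    "czechia": "Czech Republic",
    "peoples republic of china": "China",
    "people's republic of china": "China",
    "pr china": "China",
    "p.r. china": "China",
    "espana": "Spain",
    "deutschland": "Germany",
    "italia": "Italy",
    "mexico city": "Mexico",
    "turkiye": "Turkey",
    "uae": "United Arab Emirates",
    "holland": "Netherlands",
    "the netherlands": "Netherlands",
}

_CANONICAL_LOWER = {c.lower(): c for c in CANONICAL_COUNTRIES}


def canonical_country(token: str, extra_aliases: dict[str, str] | None = None) -> str | None:
    """Resolve a raw affiliation token to a canonical country name.

    Returns None when the token matches neither the canonical vocabulary nor
    the alias table (such tokens contribute no country).
    """
    t = token.strip().rstrip(".").strip().lower()
    if not t:
        return None
    if extra_aliases:
        lowered = {k.lower(): v for k, v in extra_aliases.items()}
        if t in lowered:
            return lowered[t]
    if t in COUNTRY_ALIASES:
        return COUNTRY_ALIASES[t]
    return _CANONICAL_LOWER.get(t)
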