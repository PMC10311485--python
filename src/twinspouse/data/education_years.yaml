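# Years of education attained per completed educational level.
# Editable default mapping; `enrolled` (still engaged in education at survey
# time) subtracts one year from the completed-level value.
FI:
  1: {label: "Primary education or junior high school", years: 9}
  2: {label: "Vocational school or comparable", years: 10}
  3: {label: "College level or comparable", years: 12}
  4: {label: "University of Applied Sciences or higher vocational schooling", years: 15}
  5: {label: "College or University", years: 16}
  aliases:
    "junior high school": 1
    "primary education or junior high school": 1
    "vocational school": 2
    "vocational school or comparable": 2
    "college level": 3
    "college level or comparable": 3
    "college level/senior high school": 3
    "senior high school": 3
    "university of applied sciences": 4
    "higher vocational schooling": 4
    "university of applied sciences or higher vocational schooling": 4
    "college or university": 5
    "university": 5
NL:
  1: {label: "Primary education", years: 6}
  2: {label: "Lower vocational schooling / Lower secondary schooling (general)", years: 10}
  3: {label: "Intermediate vocational schooling / higher secondary schooling", years: 13}
  4: {label: "Higher vocational schooling", years: 15}
  5: {label: "University", years: 16}
  aliases:
    "primary education": 1
    "primary school only": 1
    "lower vocational schooling": 2
    "lower secondary schooling (general)": 2
    "lower vocational schooling / lower secondary schooling (general)": 2
    "intermediate vocational schooling": 3
    "intermediate/higher secondary schooling (general)": 3
    "higher secondary schooling": 3
    "intermediate vocational schooling / higher secondary schooling": 3
    "higher vocational schooling": 4
    "university": 5
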