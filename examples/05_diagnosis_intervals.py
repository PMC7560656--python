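"""Parse relative time expressions in diagnosis statements into calendar
intervals and intersect multiple statements from one user."""

from datetime import date

from circadia import parse_tod, user_diagnosis_interval

post = date(2018, 3, 15)
for text in (
    "I was diagnosed with depression 2 weeks ago",
    "diagnosed with depression today",
    "I have been recently diagnosed with depression",
    "got my diagnosis in 2014",
    "no time expression here",
):
    interval = parse_tod(text, post)
    span = f"[{interval.start} .. {interval.end}]" if interval else "none"
    print(f"  {text!r:50s} -> {span}")

statements = [
    ("diagnosed 2 weeks ago", post),
    ("I was diagnosed recently", post),
]
combined = user_diagnosis_interval(statements)
print(
    f"\nintersection of both statements: [{combined.start} .. {combined.end}]"
    " — the diagnosis most likely falls where all statements agree."
)
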