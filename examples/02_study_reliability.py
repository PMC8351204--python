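"""Grading a toxicity study and looking up its reliability likelihood.

A 90-day study that fails two of the sixteen minimum-inclusion rules is
grade 4; crossed with an expert opinion score of 4 the lookup grid gives
a Study Reliability Likelihood of 0.9 — i.e. the study's conclusion can
be weighted as 90% reliable in evidence combination.
"""

from readacross import MinisAssessment, reliability_likelihood

assessment = MinisAssessment.from_string("PPPPPPPPPPPPPPFF")
print(f"rule outcomes: 14 pass / 2 fail  ->  MINIS grade {assessment.grade}")

for opinion in (5, 4, 3, 2, 1):
    srl = reliability_likelihood(assessment.grade, opinion)
    print(f"  opinion score {opinion}: study reliability likelihood {srl:.2f}")

print()
print("Reliability falls with worsening expert opinion at a fixed grade;")
print("a summary-only record (grade 1) with the worst opinion bottoms out at 0.5.")
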