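"""Filter a ranked sentence list by keyword, as a user would do
interactively from a topic cloud.

Matching is at the stem level, so a query like "diabetes" also matches
"diabetic". The filtered list keeps the original ranking order, giving
a query-specific summary.
"""

import mintsum as ms

vocab = ms.ControlledVocabulary()
for term, cat in [("diabet", "disease"), ("insulin", "chemical"),
                  ("retinopathi", "disease")]:
    vocab.add(term, cat)
index = ms.IdfIndex(n_docs=100, df={"diabet": 40, "insulin": 25, "retinopathi": 5})

doc = ms.preprocess_document(
    ms.RawDocument(
        "case",
        body=(
            "A diabetic patient presented with blurred vision. "
            "Insulin therapy was adjusted on admission. "
            "Fundoscopy confirmed diabetic retinopathy. "
            "The patient was discharged after stabilization. "
            "Follow-up showed improved glycemic control."
        ),
    ),
    vocab,
    ms.default_stopwords(),
)

ranked, _ = ms.summarize(doc, None, index)
print("full ranking:")
for r in ranked:
    print(f"  {r.normalized_score:.2f}  {r.raw}")

for keyword in ("diabetes", "insulin"):
    hits = ms.filter_sentences_by_keyword(ranked, doc, keyword)
    print(f"\nkeyword {keyword!r} -> {len(hits)} sentence(s):")
    for r in hits:
        print(f"  {r.normalized_score:.2f}  {r.raw}")
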