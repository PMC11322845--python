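# Default helmet-status term library.
#
# Three categories of surface phrases matched as raw, case-insensitive
# substrings of the narrative (no word boundaries, no stemming).  All
# phrases are stored pre-normalized: lower case, internal whitespace
# collapsed, no leading/trailing whitespace.  Punctuation and symbol
# tokens (+ / ? / - , &) are meaningful and preserved.
#
# Editorial notes on the curated source list:
#   * "wore helmet" and "-helmet" each appeared twice in the source
#     list; they are stored once here (the loader would deduplicate
#     within-category repeats anyway).
#   * "full helmet" appeared in the source with a stray leading space,
#     which normalization removes.
#   * "not wearig" is a deliberately retained truncated misspelling
#     ("was not wearig a helmet" narratives).
#   * "helmetd", "whelmet", "+ helmemt", "wihtout a helmet",
#     "not weariing helmet", "not wearinng a helmet" are deliberate
#     misspellings observed in real narratives.
wearing:
  - "with a helmet"
  - "with helmet"
  - "positive for helmet"
  - "positive for a helmet"
  - "helmeted"
  - "wearing helmet"
  - "wearing a helmet"
  - "w/ helmet"
  - "w helmet"
  - "wore helmet"
  - "w/helmet"
  - "w/ a helmet"
  - "had on a helmet"
  - "had on helmet"
  - "had helmet"
  - "had a helmet"
  - "his helmet"
  - "her helmet"
  - "pt helmet"
  - "pts helmet"
  - "was wearing a helmet"
  - ",helmet,"
  - "helmetd"
  - "whelmet"
  - "cracked helmet"
  - "cracking helmet"
  - "helmet cracked"
  - "helmet on"
  - "broke helmet"
  - "helmet broke"
  - "breaking helmet"
  - "positive helmet"
  - "wearing a bike helmet"
  - "wearing a full face helmet"
  - "wearing full face helmet"
  - "+helmet"
  - "+ helmet"
  - "including helmet"
  - "full helmet"
  - "+full helmet"
  - "+ full helmet"
  - "+full bike helmet"
  - "+ full bike helmet"
  - "pt's helmet"
  - "helmet fell"
  - "smashed helmet"
  - "plus helmet"
  - "helmet was fractured"
  - "helmet was broken"
  - "+ bike helmet"
  - "+bike helmet"
  - "wearing bike helmet"
  - "+ helmemt"
  - "endorses helmet"
  - "helmet went off"
  - "full face mask helmet"
  - "& helmet"
  - "helmet was reported to be cracked"
not_wearing:
  - "no helmet"
  - "without a helmet"
  - "without helmet"
  - "negative for helmet"
  - "negative for a helmet"
  - "not helmeted"
  - "-helmet"
  - "- helmet"
  - "not wearing helmet"
  - "not wearing a helmet"
  - "unhelmeted"
  - "w/o helmet"
  - "did not have on a helmet"
  - "no wearing helmet"
  - "did not have a helmet"
  - "did not have helmet"
  - "w/o a helmet"
  - "without wearing helmet"
  - "without wearing a helmet"
  - "wihtout a helmet"
  - "removed helmet"
  - "denied helmet"
  - "denied use of helmet"
  - "denied use of a helmet"
  - "helmetless"
  - "w/out helmet"
  - "denies helmet"
  - "with out helmet"
  - "with out a helmet"
  - "not wear a helmet"
  - "not wear helmet"
  - "wo a helmet"
  - "not weariing helmet"
  - "not wearinng a helmet"
  - "not wearig"
  - "negative helmet"
unknown:
  - "unsure if helmet"
  - "unsure if helmeted"
  - "unsure if pt wearing helmet"
  - "unsure if pt wearing a helmet"
  - "unsure if pt was wearing helmet"
  - "unsure if pt was wearing a helmet"
  - "unknown if helmet"
  - "helmet unknown"
  - "unknown helmet"
  - "no mention of helmet"
  - "unk helmet"
  - "helmet unk"
  - "helmet ns"
  - "ns helmet"
  - "?helmet"
  - "? helmet"
  - "helmet?"
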