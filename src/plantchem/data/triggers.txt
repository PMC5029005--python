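# Trigger word lists for the rule-based plant-chemical relation model.
# Sections: [active] transitive active forms (verbal rule structure 1),
# [passive] transitive passive / past-participle forms (verbal structure 2
# and the relative rule's participles), [intransitive] (verbal structure 3),
# [gerund] (relative rule structure 2).

[active]
contain, contains, contained
have, has, had
involve, involves, involved
incorporate, incorporates, incorporated
possess, possesses, possessed
encompass, encompasses, encompassed
subsume, subsumes, subsumed
comprise, comprises, comprised
embody, embodies, embodied
embrace, embraces, embraced
include, includes, included
cover, covers, covered
compose, composes, composed
originate, originates, originated
produce, produces, produced
derive, derives, derived
accumulate, accumulates, accumulated
release, releases, released

[passive]
contained, involved, incorporated, possessed
encompassed, subsumed, comprised, embodied
embraced, included, covered, composed, produced
originated, derived, accumulated, released, isolated
extracted, separated, detached, split, segregated
obtained, found, gained, discovered, uncovered, identified

[intransitive]
consist, consists

[gerund]
containing, involving, incorporating, possessing
encompassing, subsuming, comprising
embracing, including, covering, composing
embodying, producing, originating, deriving
accumulating, releasing, having, consisting
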