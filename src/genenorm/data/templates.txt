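# Sentence templates for the synthetic corpus generator.
# Format: <category>\t<template>. Placeholders: {G} gene mention, {F} family
# mention, {D} domain mention, {S} species name, {A} abbreviation definition
# (long form followed by parenthesized short form), {C} composite mention.
title	Regulation of {G} in {S} cells.
title	{G} and {G} interact in {S} tissue.
title	A role for {G} in {S} development.
title	Characterization of the {F} in {S}.
gene	The {G} gene is highly expressed in {S} liver.
gene	We found that {G} binds {G} in vitro.
gene	Mutations in {G} were identified in affected individuals.
gene	Expression of {G} was measured by northern blot.
gene	Overexpression of {G} increased proliferation.
gene	Loss of {G} impaired signaling in {S} cells.
gene	{G} phosphorylates {G} at conserved residues.
abbrev	{A} was cloned and sequenced.
abbrev	We studied {A} in detail.
family	Members of the {F} are conserved across species.
family	The {F} includes several closely related members.
family	Expression of the {F} was broadly reduced.
domain	The protein contains a {D} near its amino terminus.
domain	Binding requires an intact {D}.
domain	A conserved {D} mediates the interaction.
composite	{C} are required for downstream signaling.
composite	Expression of {C} was reduced in mutant animals.
filler	These results suggest a new regulatory mechanism.
filler	Samples were collected and analyzed in detail.
filler	The clinical relevance of these findings remains to be determined.
filler	Further studies will be needed to confirm this observation.
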