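# Synthetic toy word-category dictionary (English stand-in).
# Format: word<TAB>label[,label...]; labels come from the fixed hierarchy
# of 7 main categories and their subcategories. Not a licensed LIWC/SC-LIWC
# dictionary -- a small synthetic lexicon for tests, examples and the
# corpus generator.
i	first_person
me	first_person
my	first_person
myself	first_person
we	first_person
our	first_person
us	first_person
you	second_person
your	second_person
yours	second_person
he	third_person
she	third_person
they	third_person
them	third_person
his	third_person
her	third_person
a	article
an	article
the	article
no	negation
not	negation
never	negation
none	negation
nothing	negation
many	quantifier
few	quantifier
some	quantifier
all	quantifier
more	quantifier
in	preposition
on	preposition
at	preposition
with	preposition
of	preposition
and	conjunction
but	conjunction
or	conjunction
because	conjunction,causation
friend	friend
buddy	friend
family	family
mother	family
father	family
talk	communication
share	communication
listen	communication,hear
help	social
accept	social
happy	positive
hope	positive
love	positive
good	positive
better	positive
smile	positive
calm	positive
grateful	positive
sad	sad
cry	sad
tears	sad
lonely	sad
grief	sad
hopeless	sad
hurt	sad
afraid	anxious
worry	anxious
anxious	anxious
nervous	anxious
fear	anxious
angry	angry
hate	angry
annoyed	angry
rage	angry
think	insight
know	insight
understand	insight
realize	insight
reason	causation
effect	causation
always	certainty
sure	certainty
certainly	certainty
maybe	tentative
perhaps	tentative
guess	tentative
see	see
look	see
watch	see
hear	hear
sound	hear
feel	feel
warm	feel
touch	feel
head	body
body	body
sleep	body
tired	body
pain	body
ill	health
medicine	health
therapy	health
doctor	health,social
pills	health
go	motion
come	motion
leave	motion
move	motion
here	space
there	space
room	space
home	space
now	time
today	time
before	time
after	time
year	time
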