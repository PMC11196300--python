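"""Compact stop-word lists (English, Dutch) and 'talking'-verb exclusions.

The word cloud removes common function words plus verbs that merely
describe the act of talking — every diary entry is about talking, so
those terms carry no content.
"""

ENGLISH_STOPWORDS = frozenset(
    """a about above after again against all am an and any are as at be because
    been before being below between both but by could did do does doing down
    during each few for from further had has have having he her here hers
    herself him himself his how i if in into is it its itself just me more most
    my myself no nor not now of off on once only or other our ours ourselves
    out over own same she should so some such than that the their theirs them
    themselves then there these they this those through to too under until up
    very was we were what when where which while who whom why will with you
    your yours yourself yourselves""".split()
)

DUTCH_STOPWORDS = frozenset(
    """aan al alles als altijd andere ben bij daar dan dat de der deze die dit
    doch doen door dus een eens en er ge geen geweest haar had heb hebben heeft
    hem het hier hij hoe hun iemand iets ik in is ja je kan kon kunnen maar me
    meer men met mij mijn moet na naar niet niets nog nu of om omdat onder ons
    ook op over reeds te tegen toch toen tot u uit uw van veel voor want waren
    was wat werd wezen wie wil worden wordt zal ze zelf zich zij zijn zo zonder
    zou""".split()
)

TALKING_VERBS = frozenset(
    """talk talks talked talking speak speaks spoke spoken speaking chat chats
    chatted chatting say says said saying tell tells told telling discuss
    discussed discussing converse conversed mention mentioned
    praten praat gepraat spreken spreek sprak gesproken zeggen zei gezegd
    vertellen vertelde verteld kletsen geklets bespreken besproken""".split()
)

STOPWORDS = {"en": ENGLISH_STOPWORDS, "nl": DUTCH_STOPWORDS}
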