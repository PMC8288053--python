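# Stop-word phrases removed during cleaning: publication boilerplate,
# journal/affiliation debris and similar non-semantic units.
et al
fig
figure
figures
table
tables
supplementary
university
department
institute
press
inc
ltd
usa
copyright
all rights reserved
doi
vol
issue
pp
www
http
https
corresponding author
received
accepted
published
journal
page
pages
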